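"""Core domain types shared by every pipeline stage.

Coordinates are 0-based half-open throughout.  VCF input is converted on
read; BED/BEDPE are native.  Breakend orientation ``+`` means the junction
retains the reference sequence *left* of ``pos`` (i.e. ``[0, pos)``), and
``-`` means it retains the sequence *right* of ``pos`` (``[pos, L)``).
Under this algebra DEL junctions are ``(+,-)``, DUP ``(-,+)``, INV
``(+,+)`` or ``(-,-)``, and TRA junctions may carry any orientation pair.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

SV_TYPES = ("DEL", "DUP", "INV", "TRA")
HISTOLOGIES = ("acral", "cutaneous", "mucosal")
GENOMIC_SUBTYPES = ("BRAF", "NRAS", "NF1", "TWT", "not-applicable")
TAD_TYPES = ("heterochromatin", "low", "repressed", "low-active", "active")
GENE_ROLES = ("oncogene", "tumor-suppressor", "cancer-gene", "other")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def chrom_sort_key(chrom: str):
    """Natural ordering: chr1 < chr2 < ... < chr10 < chrX < chrY."""
    m = re.match(r"(?:chr)?(\d+|[XYM]T?)$", chrom, flags=re.IGNORECASE)
    if m:
        tok = m.group(1).upper()
        if tok.isdigit():
            return (0, int(tok), chrom)
        return (0, {"X": 100, "Y": 101, "M": 102, "MT": 102}[tok], chrom)
    return (1, 0, chrom)


class GenomeRef:
    """Reference genome: ordered chromosomes, lengths, and sequence access.

    ``fetch`` returns an uppercase string over {A,C,G,T,N}; queries are
    clipped at chromosome ends and rejected for unknown chromosomes.
    """

    def __init__(
        self,
        chrom_names: Iterable[str],
        chrom_lengths: Mapping[str, int],
        sequence_access: Callable[[str, int, int], str] | None = None,
    ):
        self.chrom_names = list(chrom_names)
        self.chrom_lengths = dict(chrom_lengths)
        for name in self.chrom_names:
            if self.chrom_lengths.get(name, 0) <= 0:
                raise ValueError(f"non-positive length for chromosome {name!r}")
        self._fetch = sequence_access

    @classmethod
    def from_sequences(cls, sequences: Mapping[str, str]) -> "GenomeRef":
        seqs = {c: s.upper() for c, s in sequences.items()}

        def _fetch(chrom: str, start: int, end: int) -> str:
            return seqs[chrom][start:end]

        return cls(list(seqs), {c: len(s) for c, s in seqs.items()}, _fetch)

    @classmethod
    def from_fasta(cls, path) -> "GenomeRef":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        names = list(fa.keys())
        lengths = {n: len(fa[n]) for n in names}

        def _fetch(chrom: str, start: int, end: int) -> str:
            return str(fa[chrom][start:end])

        return cls(names, lengths, _fetch)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        if chrom not in self.chrom_lengths:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if self._fetch is None:
            raise RuntimeError("GenomeRef has no sequence access")
        length = self.chrom_lengths[chrom]
        start = max(0, min(start, length))
        end = max(start, min(end, length))
        seq = self._fetch(chrom, start, end).upper()
        return revcomp(seq) if strand == "-" else seq

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())


@dataclass(frozen=True, order=False)
class Breakend:
    chrom: str
    pos: int
    orient: str  # "+" retains [0, pos); "-" retains [pos, L)

    def __post_init__(self):
        if self.orient not in ("+", "-"):
            raise ValueError(f"invalid orientation {self.orient!r}")
        if self.pos < 0:
            raise ValueError(f"negative breakend position {self.pos}")

    def sort_key(self):
        return (*chrom_sort_key(self.chrom), self.pos)


@dataclass(frozen=True)
class SVCall:
    """One caller's somatic rearrangement as an oriented breakend pair.

    ``b1`` precedes ``b2`` in (chromosome order, position); ``size`` is
    ``b2.pos - b1.pos`` for intrachromosomal calls and None for
    interchromosomal (always typed TRA).
    """

    sample_id: str
    caller_id: str
    b1: Breakend
    b2: Breakend
    svtype: str

    def __post_init__(self):
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown svtype {self.svtype!r}")
        if self.b1.sort_key() > self.b2.sort_key():
            raise ValueError("breakends out of canonical order")
        if not self.intrachromosomal and self.svtype != "TRA":
            raise ValueError("interchromosomal calls must be typed TRA")

    @classmethod
    def create(cls, sample_id, caller_id, b1: Breakend, b2: Breakend, svtype: str) -> "SVCall":
        """Build a call, reordering breakends into canonical order."""
        if b1.sort_key() > b2.sort_key():
            b1, b2 = b2, b1
        return cls(sample_id, caller_id, b1, b2, svtype)

    @property
    def intrachromosomal(self) -> bool:
        return self.b1.chrom == self.b2.chrom

    @property
    def size(self) -> int | None:
        if not self.intrachromosomal:
            return None
        return self.b2.pos - self.b1.pos

    @property
    def orient_pair(self) -> tuple[str, str]:
        return (self.b1.orient, self.b2.orient)

    def span(self) -> tuple[str, int, int]:
        """Intrachromosomal footprint as (chrom, start, end), half-open."""
        if not self.intrachromosomal:
            raise ValueError("interchromosomal call has no single-chromosome span")
        return (self.b1.chrom, self.b1.pos, self.b2.pos)


@dataclass(frozen=True)
class ConsensusSV:
    """A rearrangement supported by >=2 callers, merged per-end medians."""

    sample_id: str
    b1: Breakend
    b2: Breakend
    svtype: str
    supporting_callers: frozenset[str]
    member_calls: tuple[SVCall, ...] = field(compare=False, default=())

    @property
    def intrachromosomal(self) -> bool:
        return self.b1.chrom == self.b2.chrom

    @property
    def size(self) -> int | None:
        if not self.intrachromosomal:
            return None
        return self.b2.pos - self.b1.pos

    @property
    def orient_pair(self) -> tuple[str, str]:
        return (self.b1.orient, self.b2.orient)

    def span(self) -> tuple[str, int, int]:
        if not self.intrachromosomal:
            raise ValueError("interchromosomal record has no single-chromosome span")
        return (self.b1.chrom, self.b1.pos, self.b2.pos)


@dataclass
class SampleMeta:
    sample_id: str
    histology: str
    genomic_subtype: str = "not-applicable"
    purity: float | None = None
    ploidy: float | None = None
    coverage: float | None = None
    normal_coverage: float | None = None
    stage: str | None = None
    signature_contributions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.histology not in HISTOLOGIES:
            raise ValueError(f"unknown histology {self.histology!r}")
        if self.genomic_subtype not in GENOMIC_SUBTYPES:
            raise ValueError(f"unknown genomic subtype {self.genomic_subtype!r}")
        if self.histology != "cutaneous" and self.genomic_subtype != "not-applicable":
            raise ValueError("genomic subtype is defined only for cutaneous samples")
        if self.purity is not None and not (0.0 <= self.purity <= 1.0):
            raise ValueError(f"purity {self.purity} outside [0, 1]")
        for sig, frac in self.signature_contributions.items():
            if not (0.0 <= frac <= 1.0):
                raise ValueError(f"signature {sig} contribution {frac} outside [0, 1]")


@dataclass(frozen=True)
class TADBoundary:
    chrom: str
    start: int
    end: int
    boundary_id: str

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("boundary start must precede end")


@dataclass(frozen=True)
class TADRegion:
    chrom: str
    start: int
    end: int
    tad_type: str

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("TAD start must precede end")
        if self.tad_type not in TAD_TYPES:
            raise ValueError(f"unknown TAD type {self.tad_type!r}")


@dataclass(frozen=True)
class ChromothripsisRegion:
    sample_id: str
    event_id: str
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class GeneAnnotation:
    gene_symbol: str
    chrom: str
    start: int
    end: int
    role: str = "other"

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("gene start must precede end")
        if self.role not in GENE_ROLES:
            raise ValueError(f"unknown gene role {self.role!r}")


@dataclass(frozen=True)
class FragileSite:
    site_name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("fragile site start must precede end")
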