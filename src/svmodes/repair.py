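"""Breakpoint-junction microhomology and repair-mechanism classification.

The homology length of a junction is the number of alternative breakpoint
placements that yield an identical derived sequence, i.e. the summed
upstream and downstream ambiguity of the join.  With breakend orientation
"+" retaining ``[0, pos)`` and "-" retaining ``[pos, L)``:

* opposite-orientation junctions (DEL-like ``(+,-)``, DUP-like ``(-,+)``)
  compare the two forward strands: h = LCP of the sequences continuing
  right of the two positions + longest common suffix of the sequences
  ending at them;
* same-orientation junctions (INV-like ``(+,+)`` / ``(-,-)``) compare one
  side against the reverse complement of the other.

Mechanism labels follow the pan-cancer microhomology cutoffs: h <= 1 bp
NHEJ, 2-9 bp MMEJ, >= 10 bp SSA (blunt h = 0 joins are grouped with NHEJ
by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import Breakend, ConsensusSV, GenomeRef, SampleMeta, revcomp

DEFAULT_WINDOW = 50

MECHANISMS = ("NHEJ", "MMEJ", "SSA", "blunt", "unclassified")


@dataclass(frozen=True)
class MechanismCutoffs:
    nhej_max: int = 1  # h <= nhej_max -> NHEJ
    mmej_max: int = 9  # nhej_max < h <= mmej_max -> MMEJ; above -> SSA
    blunt_separate: bool = False  # report h == 0 apart from NHEJ


@dataclass(frozen=True)
class JunctionHomology:
    sv: ConsensusSV
    homology_len: int
    homology_seq: str
    mechanism: str


def _match_len(a: str, b: str) -> int:
    """Length of the common prefix, stopping at the first N base."""
    n = 0
    for x, y in zip(a, b):
        if x != y or x == "N" or y == "N":
            break
        n += 1
    return n


def junction_homology(
    sv: ConsensusSV,
    genome: GenomeRef,
    window: int = DEFAULT_WINDOW,
    cutoffs: MechanismCutoffs = MechanismCutoffs(),
) -> JunctionHomology:
    """Reference microhomology at an SV junction, capped at ``window``
    bases per side, with the resulting mechanism label."""
    b1, b2 = sv.b1, sv.b2
    for b in (b1, b2):
        if b.chrom not in genome or not (0 <= b.pos <= genome.chrom_lengths[b.chrom]):
            raise ValueError(f"breakend {b} outside genome")
    p1, p2 = b1.pos, b2.pos
    c1, c2 = b1.chrom, b2.chrom

    if b1.orient != b2.orient:
        # both strands read forward across the junction
        right = _match_len(genome.fetch(c1, p1, p1 + window), genome.fetch(c2, p2, p2 + window))
        left = _match_len(
            genome.fetch(c1, p1 - window, p1)[::-1],
            genome.fetch(c2, p2 - window, p2)[::-1],
        )
        seq = genome.fetch(c1, p1 - left, p1 + right)
    else:
        # one side is reverse-complemented in the derived junction
        right = _match_len(
            genome.fetch(c1, p1, p1 + window),
            revcomp(genome.fetch(c2, p2 - window, p2)),
        )
        left = _match_len(
            genome.fetch(c1, p1 - window, p1)[::-1],
            revcomp(genome.fetch(c2, p2, p2 + window))[::-1],
        )
        seq = genome.fetch(c1, p1 - left, p1 + right)
    h = min(left + right, window)
    return JunctionHomology(sv, h, seq[: h], classify_mechanism(h, cutoffs))


def classify_mechanism(h: int, cutoffs: MechanismCutoffs = MechanismCutoffs()) -> str:
    """Repair-mechanism label from a homology length."""
    if h < 0:
        raise ValueError("homology length must be non-negative")
    if h == 0 and cutoffs.blunt_separate:
        return "blunt"
    if h <= cutoffs.nhej_max:
        return "NHEJ"
    if h <= cutoffs.mmej_max:
        return "MMEJ"
    return "SSA"


def nhej_ssa_ratio(n_nhej: int, n_ssa: int) -> float:
    """Pseudocounted ratio (NHEJ + 1) / (SSA + 1), defined for zero SSA."""
    return (n_nhej + 1) / (n_ssa + 1)


def mechanism_profile(
    consensus: Iterable[ConsensusSV],
    genome: GenomeRef,
    meta: Sequence[SampleMeta] | None = None,
    window: int = DEFAULT_WINDOW,
    cutoffs: MechanismCutoffs = MechanismCutoffs(),
    signature_id: str | None = None,
    signature_cutoff: float = 0.06,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-sample mechanism counts and NHEJ:SSA ratio; optionally a
    Mann-Whitney comparison of the ratio by signature presence."""
    from .cohort_io import signature_present

    counts: dict[str, dict[str, int]] = {}
    if meta is not None:
        for m in meta:
            counts[m.sample_id] = {mech: 0 for mech in MECHANISMS}
    for sv in consensus:
        jh = junction_homology(sv, genome, window, cutoffs)
        row = counts.setdefault(sv.sample_id, {mech: 0 for mech in MECHANISMS})
        row[jh.mechanism] += 1
    rows = []
    for sid in sorted(counts):
        row = {"sample_id": sid, **counts[sid]}
        row["nhej_ssa_ratio"] = nhej_ssa_ratio(row["NHEJ"], row["SSA"])
        rows.append(row)
    profile = pd.DataFrame(rows, columns=["sample_id", *MECHANISMS, "nhej_ssa_ratio"])

    comparison = None
    if meta is not None and signature_id is not None:
        from .landscape import compare_groups

        grouping = {
            m.sample_id: (
                "signature+" if signature_present(m, signature_id, signature_cutoff) else "signature-"
            )
            for m in meta
        }
        values = dict(zip(profile["sample_id"], profile["nhej_ssa_ratio"]))
        comparison = compare_groups(values, grouping, method="mann-whitney", fdr="none")
    return profile, comparison
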