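"""Readers/writers for the cohort file formats, plus sample-level QC.

Internal coordinates are 0-based half-open.  VCF positions are converted
on read (POS-1 / END-1 for the two breakends of a symbolic record);
BED/BEDPE coordinates are used natively.  All tabular output is TSV with
a versioned ``#svmodes`` header line.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .model import (
    Breakend,
    ChromothripsisRegion,
    FragileSite,
    GeneAnnotation,
    SampleMeta,
    SVCall,
    TADBoundary,
    TADRegion,
)

logger = logging.getLogger(__name__)

TABLE_MAGIC = "#svmodes_table_v1"
BEDPE_MAGIC = "#svmodes_bedpe_v1"

# ---------------------------------------------------------------------------
# SV call ingestion
# ---------------------------------------------------------------------------

_BND_RE = re.compile(
    r"^(?:(?P<t5>[A-Za-z.*]+)(?P<br5>[\[\]])(?P<chr5>[^:\[\]]+):(?P<pos5>\d+)(?P=br5)"
    r"|(?P<br3>[\[\]])(?P<chr3>[^:\[\]]+):(?P<pos3>\d+)(?P=br3)(?P<t3>[A-Za-z.*]+))$"
)

_SYMBOLIC_TYPES = {"DEL": ("+", "-"), "DUP": ("-", "+"), "INV": ("+", "+")}


def _parse_bnd_alt(alt: str):
    """Return (local_orient, mate_chrom, mate_pos0, mate_orient) or None."""
    m = _BND_RE.match(alt)
    if not m:
        return None
    if m.group("t5") is not None:  # t[p[ or t]p]
        local_orient = "+"
        bracket, chrom, pos = m.group("br5"), m.group("chr5"), int(m.group("pos5"))
    else:  # [p[t or ]p]t
        local_orient = "-"
        bracket, chrom, pos = m.group("br3"), m.group("chr3"), int(m.group("pos3"))
    mate_orient = "-" if bracket == "[" else "+"
    return local_orient, chrom, pos - 1, mate_orient


def read_sv_calls(path, format: str, caller_id: str, sample_id: str) -> list[SVCall]:
    """Read one caller's call set for one sample.

    ``format`` is ``"vcf-bnd"`` (VCF with BND and/or symbolic ALT records)
    or ``"bedpe"``.  BND mate pairs are resolved to single records; calls
    with an unparseable ALT or unknown SV type are skipped with a logged
    warning.
    """
    if format == "vcf-bnd":
        return _read_vcf(path, caller_id, sample_id)
    if format == "bedpe":
        return read_bedpe(path, caller_id=caller_id, sample_id=sample_id)
    raise ValueError(f"unknown SV call format {format!r}")


def _read_vcf(path, caller_id: str, sample_id: str) -> list[SVCall]:
    import pysam

    calls: list[SVCall] = []
    seen_junctions: set[frozenset] = set()
    n_rejected = 0
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            svtype = rec.info.get("SVTYPE")
            alts = rec.alts or ()
            if not alts:
                n_rejected += 1
                continue
            alt = str(alts[0])
            if alt.startswith("<"):
                sym = alt.strip("<>")
                if sym not in _SYMBOLIC_TYPES:
                    n_rejected += 1
                    logger.warning("unknown symbolic ALT %s at %s:%d", alt, rec.chrom, rec.pos)
                    continue
                end0 = _symbolic_end(rec)
                if end0 is None:
                    n_rejected += 1
                    logger.warning("symbolic record without END/SVLEN at %s:%d", rec.chrom, rec.pos)
                    continue
                o1, o2 = _SYMBOLIC_TYPES[sym]
                b1 = Breakend(rec.chrom, rec.start, o1)
                b2 = Breakend(rec.chrom, end0, o2)
                calls.append(SVCall.create(sample_id, caller_id, b1, b2, sym))
            elif "[" in alt or "]" in alt:
                parsed = _parse_bnd_alt(alt)
                if parsed is None:
                    n_rejected += 1
                    logger.warning("unresolvable BND ALT %r at %s:%d; record skipped", alt, rec.chrom, rec.pos)
                    continue
                local_orient, mchrom, mpos, morient = parsed
                b_local = Breakend(rec.chrom, rec.start, local_orient)
                b_mate = Breakend(mchrom, mpos, morient)
                key = frozenset([(b_local.chrom, b_local.pos, b_local.orient), (b_mate.chrom, b_mate.pos, b_mate.orient)])
                if key in seen_junctions:
                    continue  # mate record of an already-emitted junction
                seen_junctions.add(key)
                btype = svtype if svtype in ("DEL", "DUP", "INV", "TRA") else "TRA"
                if b_local.chrom != b_mate.chrom:
                    btype = "TRA"
                calls.append(SVCall.create(sample_id, caller_id, b_local, b_mate, btype))
            else:
                n_rejected += 1
    if n_rejected:
        logger.warning("%s: %d records rejected", path, n_rejected)
    return calls


def _symbolic_end(rec) -> int | None:
    # rec.stop is pysam's 0-based exclusive END; the second breakend sits
    # at END-1 so that size == END-1 - (POS-1).
    end = rec.info.get("END", rec.stop)
    if end is not None and end > rec.start + 1:
        return int(end) - 1
    svlen = rec.info.get("SVLEN")
    if svlen is not None:
        if isinstance(svlen, (tuple, list)):
            svlen = svlen[0]
        return rec.start + abs(int(svlen))
    return None


# ---------------------------------------------------------------------------
# BEDPE
# ---------------------------------------------------------------------------

_BEDPE_COLS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2", "svtype", "sample_id", "caller_id",
]


def read_bedpe(path, caller_id: str | None = None, sample_id: str | None = None) -> list[SVCall]:
    calls: list[SVCall] = []
    n_rejected = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 10:
                raise ValueError(f"BEDPE line with {len(f)} fields: {line!r}")
            svtype = f[10] if len(f) > 10 else "TRA"
            if svtype not in ("DEL", "DUP", "INV", "TRA"):
                n_rejected += 1
                continue
            sid = sample_id or (f[11] if len(f) > 11 else "")
            cid = caller_id or (f[12] if len(f) > 12 else "")
            b1 = Breakend(f[0], int(f[1]), f[8])
            b2 = Breakend(f[3], int(f[4]), f[9])
            calls.append(SVCall.create(sid, cid, b1, b2, svtype))
    if n_rejected:
        logger.warning("%s: %d records with unknown svtype rejected", path, n_rejected)
    return calls


def write_bedpe(calls: Iterable, path) -> None:
    """Write SVCall or ConsensusSV records as 13-column BEDPE."""
    with open(path, "w") as fh:
        fh.write(BEDPE_MAGIC + "\n")
        fh.write("#" + "\t".join(_BEDPE_COLS) + "\n")
        for i, c in enumerate(calls):
            caller = getattr(c, "caller_id", None)
            if caller is None:
                caller = ",".join(sorted(c.supporting_callers))
            row = [
                c.b1.chrom, c.b1.pos, c.b1.pos + 1,
                c.b2.chrom, c.b2.pos, c.b2.pos + 1,
                f"sv{i}", ".", c.b1.orient, c.b2.orient,
                c.svtype, c.sample_id, caller,
            ]
            fh.write("\t".join(map(str, row)) + "\n")


# ---------------------------------------------------------------------------
# Annotation tracks (BED-like)
# ---------------------------------------------------------------------------

def _iter_bed(path):
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            yield line.rstrip("\n").split("\t")


def read_boundaries(path) -> list[TADBoundary]:
    out = []
    for i, f in enumerate(_iter_bed(path)):
        name = f[3] if len(f) > 3 else f"boundary_{i}"
        out.append(TADBoundary(f[0], int(f[1]), int(f[2]), name))
    return out


def read_tads(path) -> list[TADRegion]:
    return [TADRegion(f[0], int(f[1]), int(f[2]), f[3]) for f in _iter_bed(path)]


def read_genes(path) -> list[GeneAnnotation]:
    return [
        GeneAnnotation(f[3], f[0], int(f[1]), int(f[2]), f[4] if len(f) > 4 else "other")
        for f in _iter_bed(path)
    ]


def read_fragile_sites(path) -> list[FragileSite]:
    return [FragileSite(f[3], f[0], int(f[1]), int(f[2])) for f in _iter_bed(path)]


def write_bed(records: Iterable, path, fields: Sequence[str]) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write("\t".join(str(getattr(r, f)) for f in fields) + "\n")


def read_chromothripsis_regions(path) -> list[ChromothripsisRegion]:
    df = read_table(path)
    return [
        ChromothripsisRegion(r.sample_id, r.event_id, r.chrom, int(r.start), int(r.end))
        for r in df.itertuples()
    ]


def write_chromothripsis_regions(regions: Iterable[ChromothripsisRegion], path) -> None:
    df = pd.DataFrame(
        [(r.sample_id, r.event_id, r.chrom, r.start, r.end) for r in regions],
        columns=["sample_id", "event_id", "chrom", "start", "end"],
    )
    write_table(df, path, kind="chromothripsis_regions")


# ---------------------------------------------------------------------------
# Versioned TSV tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, kind: str = "table") -> None:
    with open(path, "w") as fh:
        fh.write(f"{TABLE_MAGIC}\t{kind}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(TABLE_MAGIC):
            fh.seek(0)
        return pd.read_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

_META_COLS = [
    "sample_id", "histology", "genomic_subtype", "purity", "ploidy",
    "coverage", "normal_coverage", "stage",
]


def write_sample_meta(samples: Iterable[SampleMeta], path) -> None:
    sigs = sorted({s for m in samples for s in m.signature_contributions})
    rows = []
    for m in samples:
        row = {c: getattr(m, c) for c in _META_COLS}
        for s in sigs:
            row[f"sig_{s}"] = m.signature_contributions.get(s, 0.0)
        rows.append(row)
    write_table(pd.DataFrame(rows), path, kind="sample_meta")


def read_sample_meta(path) -> list[SampleMeta]:
    df = read_table(path)
    sig_cols = [c for c in df.columns if c.startswith("sig_")]
    out = []
    for r in df.itertuples():
        contrib = {c[4:]: float(getattr(r, c)) for c in sig_cols if pd.notna(getattr(r, c))}
        out.append(
            SampleMeta(
                sample_id=str(r.sample_id),
                histology=str(r.histology),
                genomic_subtype=str(r.genomic_subtype) if pd.notna(r.genomic_subtype) else "not-applicable",
                purity=None if pd.isna(r.purity) else float(r.purity),
                ploidy=None if pd.isna(r.ploidy) else float(r.ploidy),
                coverage=None if pd.isna(r.coverage) else float(r.coverage),
                normal_coverage=None if pd.isna(r.normal_coverage) else float(r.normal_coverage),
                stage=None if pd.isna(r.stage) else str(r.stage),
                signature_contributions=contrib,
            )
        )
    return out


def read_expression(path) -> pd.DataFrame:
    """Genes x samples expression matrix (first column = gene symbol)."""
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(TABLE_MAGIC):
            fh.seek(0)
        return pd.read_csv(fh, sep="\t", index_col=0)


def write_expression(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{TABLE_MAGIC}\texpression\n")
        df.to_csv(fh, sep="\t")


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Sample-level QC
# ---------------------------------------------------------------------------

def qc_filter(
    samples: Sequence[SampleMeta],
    min_cov: float = 20.0,
    min_purity: float = 0.20,
) -> tuple[list[SampleMeta], pd.DataFrame]:
    """Retain samples with coverage >= min_cov (tumor and, when present,
    normal) and purity >= min_purity; thresholds inclusive.

    Returns (retained, report); the report lists every excluded sample
    with the reason, including samples with missing purity or coverage.
    """
    retained: list[SampleMeta] = []
    report_rows = []
    for m in samples:
        reasons = []
        if m.coverage is None:
            reasons.append("missing coverage")
        elif m.coverage < min_cov:
            reasons.append(f"coverage {m.coverage} < {min_cov}")
        if m.normal_coverage is not None and m.normal_coverage < min_cov:
            reasons.append(f"normal coverage {m.normal_coverage} < {min_cov}")
        if m.purity is None:
            reasons.append("missing purity")
        elif m.purity < min_purity:
            reasons.append(f"purity {m.purity} < {min_purity}")
        if reasons:
            report_rows.append({"sample_id": m.sample_id, "reason": "; ".join(reasons)})
        else:
            retained.append(m)
    report = pd.DataFrame(report_rows, columns=["sample_id", "reason"])
    return retained, report


def signature_present(meta: SampleMeta, signature_id: str, cutoff: float = 0.06) -> bool:
    """Presence call: contribution >= cutoff (missing signature = 0)."""
    return meta.signature_contributions.get(signature_id, 0.0) >= cutoff
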