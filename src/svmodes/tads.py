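"""TAD-boundary disruption: BA-SV detection, functional adjacency,
boundary recurrence, and the size-preserving permutation null.

A boundary-affecting SV (BA-SV) is an intrachromosomal SV shorter than
2 Mb whose span fully contains a TAD boundary.  The permutation null
relocates every eligible SV anywhere in the genome while preserving its
exact size (chromosome drawn proportionally to length minus size, start
uniform), and the empirical p uses the strict ">" of the observed count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import ContingencyTable
from .model import (
    ChromothripsisRegion,
    ConsensusSV,
    FragileSite,
    GeneAnnotation,
    GenomeRef,
    TADBoundary,
    TADRegion,
)

logger = logging.getLogger(__name__)

DEFAULT_MAX_SIZE = 2_000_000
EVENT_CLASSES = ("DEL", "DUP", "INV", "TRA", "complex")


@dataclass(frozen=True)
class BASVRecord:
    sample_id: str
    sv: ConsensusSV
    boundary_id: str
    adjacent_tad_types: tuple[str | None, str | None]
    adjacent_genes: tuple[GeneAnnotation, ...]
    event_class: str


class _BoundaryIndex:
    """Per-chromosome sorted boundary arrays for containment queries.

    Boundaries are non-overlapping within a reference set, so starts and
    ends are co-sorted and a (start >= s, end <= e) range query reduces
    to two binary searches.
    """

    def __init__(self, boundaries: Sequence[TADBoundary]):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[TADBoundary]]] = {}
        per_chrom: dict[str, list[TADBoundary]] = {}
        for b in boundaries:
            per_chrom.setdefault(b.chrom, []).append(b)
        for chrom, bs in per_chrom.items():
            bs.sort(key=lambda b: b.start)
            for prev, cur in zip(bs, bs[1:]):
                if cur.start < prev.end:
                    raise ValueError(f"overlapping boundaries on {chrom}")
            self.by_chrom[chrom] = (
                np.array([b.start for b in bs]),
                np.array([b.end for b in bs]),
                bs,
            )

    def contained(self, chrom: str, start: int, end: int) -> list[TADBoundary]:
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return []
        starts, ends, bs = entry
        lo = int(np.searchsorted(starts, start, side="left"))
        hi = int(np.searchsorted(ends, end, side="right"))
        return bs[lo:hi] if hi > lo else []

    def count_hits(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Boolean: does each [start, end) fully contain >=1 boundary."""
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return np.zeros(len(starts), dtype=bool)
        bstarts, bends, _ = entry
        lo = np.searchsorted(bstarts, starts, side="left")
        hi = np.searchsorted(bends, ends, side="right")
        return hi > lo


def eligible_svs(
    consensus: Iterable[ConsensusSV], max_size: int = DEFAULT_MAX_SIZE
) -> list[ConsensusSV]:
    """Intrachromosomal SVs with size strictly below the cutoff."""
    return [r for r in consensus if r.intrachromosomal and r.size < max_size]


def _overlapping_sv_ids(consensus: Sequence[ConsensusSV]) -> set[int]:
    """Indices of SVs whose footprint overlaps another SV of the same
    sample (interchromosomal footprints are their two breakend points)."""
    intervals: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
    for idx, sv in enumerate(consensus):
        if sv.intrachromosomal:
            chrom, s, e = sv.span()
            intervals.setdefault((sv.sample_id, chrom), []).append((s, max(e, s + 1), idx))
        else:
            for b in (sv.b1, sv.b2):
                intervals.setdefault((sv.sample_id, b.chrom), []).append((b.pos, b.pos + 1, idx))
    overlapping: set[int] = set()
    for ivs in intervals.values():
        ivs.sort()
        active: list[tuple[int, int]] = []  # (end, idx) heap-free sweep
        for s, e, idx in ivs:
            active = [(ae, ai) for ae, ai in active if ae > s]
            for _ae, ai in active:
                if ai != idx:
                    overlapping.add(ai)
                    overlapping.add(idx)
            active.append((e, idx))
    return overlapping


def detect_ba_svs(
    consensus: Sequence[ConsensusSV],
    boundaries: Sequence[TADBoundary],
    tads: Sequence[TADRegion] = (),
    genes: Sequence[GeneAnnotation] = (),
    chromothripsis_regions: Sequence[ChromothripsisRegion] = (),
    max_size: int = DEFAULT_MAX_SIZE,
) -> list[BASVRecord]:
    """One record per (eligible SV, fully contained boundary) pair.

    Adjacent TADs are the regions whose edges touch the boundary on each
    side (missing adjacency is recorded as None with a warning); adjacent
    genes are those overlapping the adjacent TADs.  The event class is
    "complex" when the SV lies in one of its sample's chromothripsis
    regions or its footprint overlaps a concomitant SV of the same
    sample, else the SV's own type.
    """
    index = _BoundaryIndex(boundaries)
    left_tad = {}
    right_tad = {}
    for t in tads:
        left_tad.setdefault((t.chrom, t.end), t)
        right_tad.setdefault((t.chrom, t.start), t)
    genes_by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    ct_by_sample: dict[str, list[ChromothripsisRegion]] = {}
    for r in chromothripsis_regions:
        ct_by_sample.setdefault(r.sample_id, []).append(r)

    consensus = list(consensus)
    overlapping = _overlapping_sv_ids(consensus)
    warned: set[str] = set()
    records: list[BASVRecord] = []
    for idx, sv in enumerate(consensus):
        if not (sv.intrachromosomal and sv.size < max_size):
            continue
        chrom, start, end = sv.span()
        hit = index.contained(chrom, start, end)
        if not hit:
            continue
        in_ct = any(
            r.chrom == chrom and start < r.end and r.start < end
            for r in ct_by_sample.get(sv.sample_id, ())
        )
        event_class = "complex" if (in_ct or idx in overlapping) else sv.svtype
        for b in hit:
            lt = left_tad.get((b.chrom, b.start))
            rt = right_tad.get((b.chrom, b.end))
            if tads and (lt is None or rt is None) and b.boundary_id not in warned:
                warned.add(b.boundary_id)
                logger.warning("boundary %s lacks an adjacent TAD on one side", b.boundary_id)
            adj_genes: list[GeneAnnotation] = []
            for t in (lt, rt):
                if t is None:
                    continue
                adj_genes.extend(
                    g for g in genes_by_chrom.get(t.chrom, ())
                    if g.start < t.end and t.start < g.end
                )
            records.append(
                BASVRecord(
                    sample_id=sv.sample_id,
                    sv=sv,
                    boundary_id=b.boundary_id,
                    adjacent_tad_types=(
                        lt.tad_type if lt else None,
                        rt.tad_type if rt else None,
                    ),
                    adjacent_genes=tuple(adj_genes),
                    event_class=event_class,
                )
            )
    return records


def count_boundary_affecting(
    consensus: Iterable[ConsensusSV],
    boundaries: Sequence[TADBoundary],
    max_size: int = DEFAULT_MAX_SIZE,
) -> int:
    """Number of eligible SVs whose span fully contains >=1 boundary."""
    index = _BoundaryIndex(boundaries)
    n = 0
    for sv in eligible_svs(consensus, max_size):
        chrom, start, end = sv.span()
        if index.contained(chrom, start, end):
            n += 1
    return n


def basv_permutation(
    consensus: Iterable[ConsensusSV],
    boundaries: Sequence[TADBoundary],
    genome: GenomeRef,
    n_perm: int = 1000,
    seed: int | None = None,
    max_size: int = DEFAULT_MAX_SIZE,
    within_chrom: bool = False,
    smoothed: bool = False,
) -> tuple[int, np.ndarray, float]:
    """Size-preserving shuffle null for the BA-SV frequency.

    Returns (observed count, null counts per permutation, p) with
    p = #{null > observed} / n_perm (strict).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    svs = eligible_svs(consensus, max_size)
    index = _BoundaryIndex(boundaries)
    observed = 0
    for sv in svs:
        chrom, start, end = sv.span()
        if index.contained(chrom, start, end):
            observed += 1
    if not svs:
        p = 1.0 / (n_perm + 1) if smoothed else 0.0
        return 0, np.zeros(n_perm, dtype=int), p

    chroms = list(genome.chrom_names)
    lengths = np.array([genome.chrom_lengths[c] for c in chroms], dtype=np.int64)
    sizes = np.array([sv.size for sv in svs], dtype=np.int64)
    rng = np.random.default_rng(seed)

    if within_chrom:
        chrom_idx_fixed = np.array([chroms.index(sv.b1.chrom) for sv in svs])
        room = lengths[chrom_idx_fixed] - sizes
        if np.any(room < 0):
            raise ValueError("an SV is larger than its own chromosome")
        chrom_idx = np.broadcast_to(chrom_idx_fixed, (n_perm, len(svs)))
        starts = rng.integers(0, room[None, :] + 1, size=(n_perm, len(svs)))
    else:
        weights = np.maximum(lengths[None, :] - sizes[:, None], 0)  # (n_sv, n_chrom)
        totals = weights.sum(axis=1)
        if np.any(totals <= 0):
            raise ValueError("an SV is larger than every chromosome")
        cdf = np.cumsum(weights, axis=1) / totals[:, None]
        u = rng.random((n_perm, len(svs)))
        chrom_idx = (u[:, :, None] > cdf[None, :, :]).sum(axis=2)
        room = lengths[chrom_idx] - sizes[None, :]
        starts = np.floor(rng.random((n_perm, len(svs))) * (room + 1)).astype(np.int64)

    ends = starts + sizes[None, :]
    null = np.zeros(n_perm, dtype=int)
    for ci, chrom in enumerate(chroms):
        mask = chrom_idx == ci
        if not mask.any():
            continue
        hits = index.count_hits(chrom, starts[mask], ends[mask])
        flat = np.zeros(mask.shape, dtype=bool)
        flat[mask] = hits
        null += flat.sum(axis=1)
    p = ((null > observed).sum() + 1) / (n_perm + 1) if smoothed else float((null > observed).mean())
    return observed, null, float(p)


def recurrence_and_adjacency(
    ba_svs: Sequence[BASVRecord],
    fragile_sites: Sequence[FragileSite] = (),
    boundaries: Sequence[TADBoundary] = (),
    recurrence_threshold: int = 5,
) -> tuple[pd.DataFrame, float, dict[str, ContingencyTable]]:
    """Boundary recurrence table, recurrent-boundary BA-SV fraction, and
    the 2x2 role-adjacency tables handed to the enrichment module.

    Recurrence is inclusive: a boundary hit in >= ``recurrence_threshold``
    distinct samples is recurrent.  Nearest fragile-site distance is the
    minimal interval gap on the same chromosome (0 when overlapping).
    """
    binfo = {b.boundary_id: b for b in boundaries}
    for r in ba_svs:
        binfo.setdefault(r.boundary_id, None)
    sites_by_chrom: dict[str, list[FragileSite]] = {}
    for s in fragile_sites:
        sites_by_chrom.setdefault(s.chrom, []).append(s)

    per_boundary: dict[str, list[BASVRecord]] = {}
    for r in ba_svs:
        per_boundary.setdefault(r.boundary_id, []).append(r)

    rows = []
    for bid in sorted(per_boundary):
        recs = per_boundary[bid]
        row = {
            "boundary_id": bid,
            "n_samples": len({r.sample_id for r in recs}),
            "n_svs": len(recs),
        }
        for cls in EVENT_CLASSES:
            row[f"n_{cls}"] = sum(r.event_class == cls for r in recs)
        site_name, dist = None, None
        bnd = binfo.get(bid)
        if bnd is not None:
            for s in sites_by_chrom.get(bnd.chrom, ()):
                gap = max(s.start - bnd.end, bnd.start - s.end, 0)
                if dist is None or gap < dist:
                    site_name, dist = s.site_name, gap
        row["nearest_fragile_site"] = site_name
        row["fragile_site_distance"] = dist
        rows.append(row)
    table = pd.DataFrame(rows)

    recurrent_ids = {
        r["boundary_id"] for r in rows if r["n_samples"] >= recurrence_threshold
    }
    n_total = len(ba_svs)
    frac_recurrent = (
        sum(r.boundary_id in recurrent_ids for r in ba_svs) / n_total if n_total else float("nan")
    )

    def _role_adjacent(rec: BASVRecord, role: str) -> bool:
        return any(g.role == role for g in rec.adjacent_genes)

    def _table(cls: str, role: str) -> ContingencyTable:
        a = sum(r.event_class == cls and _role_adjacent(r, role) for r in ba_svs)
        b_ = sum(r.event_class == cls and not _role_adjacent(r, role) for r in ba_svs)
        c = sum(r.event_class != cls and _role_adjacent(r, role) for r in ba_svs)
        d = sum(r.event_class != cls and not _role_adjacent(r, role) for r in ba_svs)
        return ContingencyTable(a, b_, c, d)

    tables = {
        "deletion_vs_tumor_suppressor": _table("DEL", "tumor-suppressor"),
        "complex_vs_oncogene": _table("complex", "oncogene"),
    }
    return table, frac_recurrent, tables


def basv_burden_correlation(
    total_svs: Mapping[str, int],
    ba_svs: Mapping[str, int],
    grouping: Mapping[str, str],
) -> pd.DataFrame:
    """Per-group Pearson correlation between global SV burden and BA-SV
    burden, with two-sided t-based p.  Zero-variance groups are flagged."""
    by_group: dict[str, list[tuple[float, float]]] = {}
    for sample, g in grouping.items():
        if sample in total_svs and sample in ba_svs:
            by_group.setdefault(g, []).append((float(total_svs[sample]), float(ba_svs[sample])))
    rows = []
    for g in sorted(by_group):
        pairs = by_group[g]
        if len(pairs) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 samples")
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        if np.std(x) == 0 or np.std(y) == 0:
            logger.warning("group %s has zero variance; correlation undefined", g)
            rows.append({"group": g, "n": len(pairs), "r": np.nan, "p": np.nan, "flagged": True})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"group": g, "n": len(pairs), "r": float(r), "p": float(p), "flagged": False})
    return pd.DataFrame(rows, columns=["group", "n", "r", "p", "flagged"])
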