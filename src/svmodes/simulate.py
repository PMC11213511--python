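"""Synthetic cohort generator with a machine-readable truth ledger.

Generates a random reference genome with a TAD/boundary/gene/fragile-site
scaffold, plants per-sample SVs (subtype-specific burdens and size
mixtures, boundary-spanning placements, clustered chromothripsis events,
and junction microhomologies realized physically in the reference
sequence), emulates multiple callers with breakpoint jitter, dropout and
false positives, and simulates an expression matrix with group-wise
correlation structure.  Every planted feature is recorded in the ledger
so downstream modules can be tested against ground truth offline.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    Breakend,
    ChromothripsisRegion,
    FragileSite,
    GeneAnnotation,
    GenomeRef,
    SampleMeta,
    SVCall,
    TADBoundary,
    TADRegion,
    TAD_TYPES,
)

_BASES = b"ACGT"
_COMP = {65: 84, 67: 71, 71: 67, 84: 65}  # A<->T, C<->G on byte values

# orientation pairs per planted junction class
_ORIENTS = {"DEL": ("+", "-"), "DUP": ("-", "+"), "INV+": ("+", "+"), "INV-": ("-", "-")}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CallerModel:
    name: str
    detection_prob: float = 0.9
    jitter_sd: float = 0.0
    fp_rate: float = 0.0  # expected false positives per sample


@dataclass(frozen=True)
class GroupSpec:
    name: str
    histology: str
    n_samples: int
    genomic_subtype: str = "not-applicable"
    burden: Mapping[str, float] = field(
        default_factory=lambda: {"DEL": 8, "DUP": 5, "INV": 6, "TRA": 12}
    )
    small_frac: Mapping[str, float] = field(default_factory=lambda: {"DEL": 0.2, "INV": 0.2})
    inter_tra_frac: float = 0.7
    chromothripsis_frac: float = 0.0
    ct_chroms_mean: float = 3.0
    ct_svs_per_event: int = 12
    sig3_frac: float = 0.0


@dataclass(frozen=True)
class GenomeConfig:
    n_chroms: int = 4
    chrom_length: int = 1_000_000
    tad_size: int = 40_000
    boundary_size: int = 5_000
    n_tads_per_chrom: int | None = None
    gene_prob: float = 0.8  # probability a TAD carries a gene
    gene_role_probs: Mapping[str, float] = field(
        default_factory=lambda: {"oncogene": 0.1, "tumor-suppressor": 0.1, "cancer-gene": 0.1, "other": 0.7}
    )
    n_fragile_sites: int = 6


@dataclass(frozen=True)
class MechanismMix:
    nhej: float = 0.55
    mmej: float = 0.35
    ssa: float = 0.10


@dataclass(frozen=True)
class SimConfig:
    genome: GenomeConfig = GenomeConfig()
    groups: tuple[GroupSpec, ...] = ()
    callers: tuple[CallerModel, ...] = (
        CallerModel("caller1"),
        CallerModel("caller2"),
        CallerModel("caller3"),
    )
    mechanism_mix: MechanismMix = MechanismMix()
    sig3_mechanism_mix: MechanismMix = MechanismMix(nhej=0.80, mmej=0.17, ssa=0.03)
    sig3_burden_log2fc: float = 0.8  # applied to DUP and TRA means
    ba_boundary_rate: float = 0.05  # probability an SV is placed across a boundary
    small_cutoff: int = 10_000
    small_size_log2_mean: float = 11.5  # ~2.9 kb
    small_size_log2_sd: float = 0.7
    large_size_log2_mean: float = 16.5  # ~93 kb
    large_size_log2_sd: float = 1.2
    min_size: int = 100
    homology_window: int = 50
    plant_homology: bool = True


def default_config(scale: float = 0.25) -> SimConfig:
    """Cohort mirroring the study's group sizes (acral 116, mucosal 64;
    cutaneous 81/55/19/20 by genomic subtype), scaled for CI speed."""

    def n(x: int) -> int:
        return max(2, round(x * scale))

    groups = (
        GroupSpec("acral", "acral", n(116), burden={"DEL": 19, "DUP": 12, "INV": 14, "TRA": 36},
                  chromothripsis_frac=0.7, ct_chroms_mean=4.0),
        GroupSpec("mucosal", "mucosal", n(64), burden={"DEL": 16, "DUP": 10, "INV": 10, "TRA": 28},
                  chromothripsis_frac=0.31, ct_chroms_mean=3.0),
        GroupSpec("BRAF", "cutaneous", n(81), genomic_subtype="BRAF",
                  burden={"DEL": 6, "DUP": 3, "INV": 4, "TRA": 10},
                  small_frac={"DEL": 0.4, "INV": 0.35}, chromothripsis_frac=0.25),
        GroupSpec("NRAS", "cutaneous", n(55), genomic_subtype="NRAS",
                  burden={"DEL": 6, "DUP": 3, "INV": 4, "TRA": 10},
                  small_frac={"DEL": 0.45, "INV": 0.4}, chromothripsis_frac=0.2),
        GroupSpec("NF1", "cutaneous", n(19), genomic_subtype="NF1",
                  burden={"DEL": 10, "DUP": 3, "INV": 4, "TRA": 10},
                  small_frac={"DEL": 0.45, "INV": 0.4}, chromothripsis_frac=0.42),
        GroupSpec("TWT", "cutaneous", n(20), genomic_subtype="TWT",
                  burden={"DEL": 6, "DUP": 3, "INV": 4, "TRA": 10},
                  small_frac={"DEL": 0.4, "INV": 0.35}, chromothripsis_frac=0.25, sig3_frac=0.25),
    )
    return SimConfig(groups=groups)


# ---------------------------------------------------------------------------
# Genome scaffold
# ---------------------------------------------------------------------------

@dataclass
class GenomeScaffold:
    sequences: dict[str, bytearray]
    tads: list[TADRegion]
    boundaries: list[TADBoundary]
    genes: list[GeneAnnotation]
    fragile_sites: list[FragileSite]

    @property
    def ref(self) -> GenomeRef:
        seqs = self.sequences

        def _fetch(chrom: str, start: int, end: int) -> str:
            return seqs[chrom][start:end].decode()

        return GenomeRef(list(seqs), {c: len(s) for c, s in seqs.items()}, _fetch)


def simulate_genome(config: SimConfig, seed: int | None = None) -> GenomeScaffold:
    """Random genome with tiled TADs, internal boundaries between
    consecutive TADs, genes inside TADs, and fragile sites."""
    g = config.genome
    rng = np.random.default_rng(seed)
    sequences: dict[str, bytearray] = {}
    tads: list[TADRegion] = []
    boundaries: list[TADBoundary] = []
    genes: list[GeneAnnotation] = []
    fragile: list[FragileSite] = []

    unit = g.tad_size + g.boundary_size
    max_fit = (g.chrom_length + g.boundary_size) // unit
    n_tads = g.n_tads_per_chrom if g.n_tads_per_chrom is not None else max_fit
    if n_tads > max_fit:
        raise ValueError(
            f"{n_tads} TADs of {g.tad_size} bp do not fit a {g.chrom_length} bp chromosome"
        )
    roles = list(g.gene_role_probs)
    role_p = np.array([g.gene_role_probs[r] for r in roles], dtype=float)
    role_p = role_p / role_p.sum()

    gi = 0
    for ci in range(g.n_chroms):
        chrom = f"chr{ci + 1}"
        seq = rng.integers(0, 4, size=g.chrom_length)
        sequences[chrom] = bytearray(bytes(_BASES[b] for b in seq.tolist()))
        # guarantee all five TAD types appear when possible
        types = [TAD_TYPES[i % len(TAD_TYPES)] for i in range(n_tads)]
        rng.shuffle(types)
        pos = 0
        for ti in range(n_tads):
            t_start, t_end = pos, pos + g.tad_size
            tads.append(TADRegion(chrom, t_start, t_end, types[ti]))
            if g.gene_prob > 0 and rng.random() < g.gene_prob:
                glen = int(g.tad_size * rng.uniform(0.05, 0.3))
                gstart = int(rng.integers(t_start, t_end - glen))
                role = roles[int(rng.choice(len(roles), p=role_p))]
                genes.append(GeneAnnotation(f"GENE{gi:04d}", chrom, gstart, gstart + glen, role))
                gi += 1
            if ti < n_tads - 1:
                boundaries.append(
                    TADBoundary(chrom, t_end, t_end + g.boundary_size, f"{chrom}_b{ti}")
                )
            pos = t_end + g.boundary_size
    for si in range(g.n_fragile_sites):
        chrom = f"chr{int(rng.integers(0, g.n_chroms)) + 1}"
        length = int(rng.integers(20_000, 80_000))
        start = int(rng.integers(0, g.chrom_length - length))
        fragile.append(FragileSite(f"FRA{si}", chrom, start, start + length))
    return GenomeScaffold(sequences, tads, boundaries, genes, fragile)


# ---------------------------------------------------------------------------
# Homology planting
# ---------------------------------------------------------------------------

class _Reservations:
    """Non-overlapping reserved windows so one junction's planted flanks
    never overwrite another's."""

    def __init__(self):
        self._by_chrom: dict[str, list[tuple[int, int]]] = {}

    def try_reserve(self, intervals: Sequence[tuple[str, int, int]]) -> bool:
        staged: list[tuple[str, int]] = []
        for chrom, s, e in intervals:
            ivs = self._by_chrom.setdefault(chrom, [])
            i = bisect.bisect_left(ivs, (s, e))
            if i > 0 and ivs[i - 1][1] > s:
                return False
            if i < len(ivs) and ivs[i][0] < e:
                return False
        for chrom, s, e in intervals:
            ivs = self._by_chrom[chrom]
            bisect.insort(ivs, (s, e))
        return True


def _other_base(rng, *avoid: int) -> int:
    choices = [b for b in _BASES if b not in avoid]
    return choices[int(rng.integers(0, len(choices)))]


def _plant_junction_homology(
    sequences: dict[str, bytearray],
    b1: Breakend,
    b2: Breakend,
    h: int,
    rng: np.random.Generator,
) -> None:
    """Mutate the reference so the junction's exact homology equals h.

    The bases continuing past the second breakend are copied from the
    first, and the flanking bases just outside the tract are forced to
    mismatch so the recovered homology is exactly h on both sides.
    """
    A, B = sequences[b1.chrom], sequences[b2.chrom]
    p1, p2 = b1.pos, b2.pos
    if b1.orient != b2.orient:
        B[p2 : p2 + h] = A[p1 : p1 + h]
        B[p2 + h] = _other_base(rng, A[p1 + h])
        B[p2 - 1] = _other_base(rng, A[p1 - 1])
    else:
        tract = bytes(_COMP[b] for b in reversed(A[p1 : p1 + h]))
        B[p2 - h : p2] = tract
        B[p2 - h - 1] = _other_base(rng, _COMP[A[p1 + h]])
        B[p2] = _other_base(rng, _COMP[A[p1 - 1]])


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class TruthLedger:
    """Every planted feature, for use as a test oracle."""

    svs: pd.DataFrame  # one row per planted SV
    samples: pd.DataFrame  # per-sample group, signature, true burdens
    false_positives: pd.DataFrame  # per emitted false-positive call


@dataclass
class SimulatedCohort:
    meta: list[SampleMeta]
    calls: dict[str, dict[str, list[SVCall]]]  # sample -> caller -> calls
    regions: list[ChromothripsisRegion]
    truth: TruthLedger

    def calls_by_sample(self) -> dict[str, list[SVCall]]:
        return {
            s: [c for caller_calls in per_caller.values() for c in caller_calls]
            for s, per_caller in self.calls.items()
        }


def _sample_size(config: SimConfig, small: bool, rng) -> int:
    mu = config.small_size_log2_mean if small else config.large_size_log2_mean
    sd = config.small_size_log2_sd if small else config.large_size_log2_sd
    size = int(2 ** rng.normal(mu, sd))
    return max(config.min_size, size)


def _mechanism_and_h(mix: MechanismMix, rng) -> tuple[str, int]:
    u = rng.random()
    if u < mix.nhej:
        return "NHEJ", int(rng.integers(0, 2))
    if u < mix.nhej + mix.mmej:
        return "MMEJ", int(rng.integers(2, 10))
    return "SSA", int(rng.integers(10, 16))


def simulate_cohort(
    config: SimConfig,
    scaffold: GenomeScaffold,
    seed: int | None = None,
) -> SimulatedCohort:
    """Plant per-sample SVs and emit per-caller call sets.

    Each true SV is detected by each caller independently with its
    detection probability, with Gaussian breakpoint jitter (resampled if
    it leaves the chromosome) and Poisson false positives per caller.
    """
    rng = np.random.default_rng(seed)
    chroms = list(scaffold.sequences)
    lengths = {c: len(s) for c, s in scaffold.sequences.items()}
    # flank windows only need to be reserved when homology is physically
    # planted; burden-only simulations place freely
    reservations = _Reservations() if config.plant_homology else None
    pad = config.homology_window + 4

    sv_rows: list[dict] = []
    sample_rows: list[dict] = []
    fp_rows: list[dict] = []
    meta: list[SampleMeta] = []
    regions: list[ChromothripsisRegion] = []
    calls: dict[str, dict[str, list[SVCall]]] = {}

    boundary_pool = scaffold.boundaries

    def _place_breakpoints(svtype: str, size: int | None, chrom_pair=None, region_pair=None):
        """Choose junction coordinates + orientations; returns (b1, b2) or
        None when no reservable placement is found."""
        for _ in range(60):
            if svtype == "TRA" and size is None:  # interchromosomal
                if region_pair is not None:
                    (c1, r1s, r1e), (c2, r2s, r2e) = region_pair
                    p1 = int(rng.integers(r1s + pad, r1e - pad))
                    p2 = int(rng.integers(r2s + pad, r2e - pad))
                else:
                    c1, c2 = rng.choice(chroms, size=2, replace=False)
                    p1 = int(rng.integers(pad, lengths[c1] - pad))
                    p2 = int(rng.integers(pad, lengths[c2] - pad))
                o1, o2 = rng.choice(["+", "-"], size=2)
                b1, b2 = Breakend(c1, p1, o1), Breakend(c2, p2, o2)
            else:
                if region_pair is not None:
                    c1, rs, re_ = region_pair[0]
                    lo, hi = rs + pad, re_ - pad - size
                else:
                    c1 = chroms[int(rng.integers(0, len(chroms)))] if chrom_pair is None else chrom_pair
                    lo, hi = pad, lengths[c1] - pad - size
                if hi <= lo:
                    continue
                p1 = int(rng.integers(lo, hi))
                p2 = p1 + size
                if svtype == "DEL":
                    o1, o2 = _ORIENTS["DEL"]
                elif svtype == "DUP":
                    o1, o2 = _ORIENTS["DUP"]
                elif svtype == "INV":
                    o1, o2 = _ORIENTS["INV+" if rng.random() < 0.5 else "INV-"]
                else:  # intrachromosomal TRA: random junction orientations
                    o1, o2 = rng.choice(["+", "-"], size=2)
                b1, b2 = Breakend(c1, p1, o1), Breakend(c1, p2, o2)
            windows = [(b1.chrom, b1.pos - pad, b1.pos + pad), (b2.chrom, b2.pos - pad, b2.pos + pad)]
            if reservations is None or reservations.try_reserve(windows):
                return b1, b2
        return None

    def _place_ba(svtype: str, size: int):
        """Place an intrachromosomal SV whose span fully contains a
        randomly chosen TAD boundary."""
        for _ in range(40):
            b = boundary_pool[int(rng.integers(0, len(boundary_pool)))]
            blen = b.end - b.start
            if size <= blen + 2 * pad:
                continue
            lo = max(pad, b.end - size + 1)
            hi = min(b.start, lengths[b.chrom] - pad - size)
            if hi <= lo:
                continue
            p1 = int(rng.integers(lo, hi + 1))
            p2 = p1 + size
            if svtype == "DEL":
                o1, o2 = _ORIENTS["DEL"]
            elif svtype == "DUP":
                o1, o2 = _ORIENTS["DUP"]
            elif svtype == "INV":
                o1, o2 = _ORIENTS["INV+" if rng.random() < 0.5 else "INV-"]
            else:
                o1, o2 = rng.choice(["+", "-"], size=2)
            b1, b2 = Breakend(b.chrom, p1, o1), Breakend(b.chrom, p2, o2)
            windows = [(b1.chrom, p1 - pad, p1 + pad), (b2.chrom, p2 - pad, p2 + pad)]
            if reservations is None or reservations.try_reserve(windows):
                return b1, b2, b.boundary_id
        return None

    sv_id = 0
    for group in config.groups:
        for i in range(group.n_samples):
            sid = f"{group.name}_{i:03d}"
            sig3 = bool(rng.random() < group.sig3_frac)
            contributions = {
                "1": float(rng.uniform(0.0, 0.3)),
                "7": float(rng.uniform(0.1, 0.6) if group.histology == "cutaneous" else rng.uniform(0.0, 0.05)),
                "3": float(rng.uniform(0.06, 0.30)) if sig3 else float(rng.uniform(0.0, 0.059)),
            }
            meta.append(
                SampleMeta(
                    sample_id=sid,
                    histology=group.histology,
                    genomic_subtype=group.genomic_subtype,
                    purity=float(rng.uniform(0.35, 0.95)),
                    ploidy=float(rng.uniform(1.8, 3.6)),
                    coverage=float(rng.uniform(30, 90)),
                    normal_coverage=float(rng.uniform(25, 60)),
                    stage=f"stage{int(rng.integers(1, 4))}",
                    signature_contributions=contributions,
                )
            )
            mech_mix = config.sig3_mechanism_mix if sig3 else config.mechanism_mix
            sample_svs: list[dict] = []

            def _add_sv(b1, b2, svtype, in_ct, event_id, spans_boundary):
                nonlocal sv_id
                mech, h = _mechanism_and_h(mech_mix, rng)
                if config.plant_homology:
                    _plant_junction_homology(scaffold.sequences, b1, b2, h, rng)
                if b1.sort_key() > b2.sort_key():
                    b1, b2 = b2, b1
                sample_svs.append(
                    {
                        "sv_id": f"sv{sv_id:06d}", "sample_id": sid,
                        "chrom1": b1.chrom, "pos1": b1.pos, "orient1": b1.orient,
                        "chrom2": b2.chrom, "pos2": b2.pos, "orient2": b2.orient,
                        "svtype": svtype,
                        "size": (b2.pos - b1.pos) if b1.chrom == b2.chrom else -1,
                        "mechanism": mech, "homology": h,
                        "in_chromothripsis": in_ct, "event_id": event_id,
                        "spans_boundary": spans_boundary,
                    }
                )
                sv_id += 1

            # --- chromothripsis events ---
            n_events = int(rng.random() < group.chromothripsis_frac)
            for ev in range(n_events):
                event_id = f"{sid}_ct{ev}"
                n_chr = min(len(chroms), max(1, int(rng.poisson(group.ct_chroms_mean - 1)) + 1))
                ev_chroms = list(rng.choice(chroms, size=n_chr, replace=False))
                ev_regions = []
                for c in ev_chroms:
                    rlen = int(rng.integers(60_000, 140_000))
                    rstart = int(rng.integers(pad, lengths[c] - rlen - pad))
                    ev_regions.append((c, rstart, rstart + rlen))
                    regions.append(ChromothripsisRegion(sid, event_id, c, rstart, rstart + rlen))
                for _ in range(group.ct_svs_per_event):
                    if len(ev_regions) >= 2 and rng.random() < 0.4:
                        r1, r2 = [ev_regions[j] for j in rng.choice(len(ev_regions), size=2, replace=False)]
                        placed = _place_breakpoints("TRA", None, region_pair=(r1, r2))
                        if placed:
                            _add_sv(*placed, "TRA", True, event_id, False)
                    else:
                        r1 = ev_regions[int(rng.integers(0, len(ev_regions)))]
                        svtype = ["DEL", "DUP", "INV"][int(rng.integers(0, 3))]
                        rlen = r1[2] - r1[1]
                        size = min(_sample_size(config, rng.random() < 0.5, rng), rlen - 3 * pad)
                        if size < config.min_size:
                            size = config.min_size
                        placed = _place_breakpoints(svtype, size, region_pair=(r1, None))
                        if placed:
                            _add_sv(*placed, svtype, True, event_id, False)

            # --- background SVs ---
            for svtype, mean in group.burden.items():
                mu = float(mean)
                if sig3 and svtype in ("DUP", "TRA"):
                    mu *= 2.0**config.sig3_burden_log2fc
                n_sv = int(rng.poisson(mu))
                for _ in range(n_sv):
                    if svtype == "TRA" and rng.random() < group.inter_tra_frac:
                        placed = _place_breakpoints("TRA", None)
                        if placed:
                            _add_sv(*placed, "TRA", False, "", False)
                        continue
                    small = rng.random() < group.small_frac.get(svtype, 0.1)
                    size = _sample_size(config, small, rng)
                    size = min(size, min(lengths.values()) // 2)
                    if config.ba_boundary_rate > 0 and rng.random() < config.ba_boundary_rate:
                        placed = _place_ba(svtype, size)
                        if placed:
                            b1, b2, bid = placed
                            _add_sv(b1, b2, svtype, False, "", True)
                            continue
                    placed = _place_breakpoints(svtype, size)
                    if placed:
                        _add_sv(*placed, svtype, False, "", False)

            sv_rows.extend(sample_svs)
            burdens = {t: sum(r["svtype"] == t for r in sample_svs) for t in ("DEL", "DUP", "INV", "TRA")}
            sample_rows.append(
                {
                    "sample_id": sid, "group": group.name, "histology": group.histology,
                    "genomic_subtype": group.genomic_subtype, "signature3": sig3,
                    "has_chromothripsis": n_events > 0,
                    **{f"true_{t}": n for t, n in burdens.items()},
                    "true_total": sum(burdens.values()),
                }
            )

            # --- caller emission ---
            per_caller: dict[str, list[SVCall]] = {}
            for caller in config.callers:
                emitted: list[SVCall] = []
                for row in sample_svs:
                    if rng.random() >= caller.detection_prob:
                        continue
                    ends = []
                    for chrom, pos, orient in (
                        (row["chrom1"], row["pos1"], row["orient1"]),
                        (row["chrom2"], row["pos2"], row["orient2"]),
                    ):
                        jp = pos
                        if caller.jitter_sd > 0:
                            for _ in range(20):
                                jp = pos + int(round(rng.normal(0, caller.jitter_sd)))
                                if 0 <= jp <= lengths[chrom]:
                                    break
                            else:
                                jp = pos
                        ends.append(Breakend(chrom, jp, orient))
                    emitted.append(SVCall.create(sid, caller.name, ends[0], ends[1], row["svtype"]))
                for _ in range(int(rng.poisson(caller.fp_rate))):
                    svtype = ["DEL", "DUP", "INV", "TRA"][int(rng.integers(0, 4))]
                    if svtype == "TRA":
                        c1, c2 = rng.choice(chroms, size=2, replace=False)
                        b1 = Breakend(c1, int(rng.integers(0, lengths[c1])), str(rng.choice(["+", "-"])))
                        b2 = Breakend(c2, int(rng.integers(0, lengths[c2])), str(rng.choice(["+", "-"])))
                    else:
                        c1 = chroms[int(rng.integers(0, len(chroms)))]
                        size = _sample_size(config, rng.random() < 0.3, rng)
                        size = min(size, lengths[c1] // 2)
                        p1 = int(rng.integers(0, lengths[c1] - size))
                        o1, o2 = _ORIENTS[svtype if svtype != "INV" else "INV+"]
                        b1, b2 = Breakend(c1, p1, o1), Breakend(c1, p1 + size, o2)
                    fp = SVCall.create(sid, caller.name, b1, b2, svtype)
                    emitted.append(fp)
                    fp_rows.append(
                        {
                            "sample_id": sid, "caller_id": caller.name,
                            "chrom1": fp.b1.chrom, "pos1": fp.b1.pos,
                            "chrom2": fp.b2.chrom, "pos2": fp.b2.pos, "svtype": svtype,
                        }
                    )
                per_caller[caller.name] = emitted
            calls[sid] = per_caller

    truth = TruthLedger(
        svs=pd.DataFrame(sv_rows),
        samples=pd.DataFrame(sample_rows),
        false_positives=pd.DataFrame(
            fp_rows, columns=["sample_id", "caller_id", "chrom1", "pos1", "chrom2", "pos2", "svtype"]
        ),
    )
    return SimulatedCohort(meta=meta, calls=calls, regions=regions, truth=truth)


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionGroup:
    name: str
    n_samples: int
    correlation: float  # latent complex-target correlation, in (-1, 1)


def simulate_expression(
    groups: Sequence[ExpressionGroup],
    complex_genes: Sequence[str] = ("MRE11", "NBN", "RAD50"),
    target_gene: str = "ATM",
    seed: int | None = None,
    base_mean: float = 1000.0,
    base_sd: float = 100.0,
    gene_noise_sd: float = 10.0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Expression matrix with block correlation between a gene complex
    and a target gene, group by group.

    A bivariate-normal latent pair with the configured correlation is
    mapped near-linearly to nonnegative expression (mean >> sd), so the
    observed complex-score/target Pearson r matches the latent r up to
    sampling error.  Returns (genes x samples matrix, sample -> group).
    """
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    labels: dict[str, str] = {}
    for grp in groups:
        if not (-1.0 < grp.correlation < 1.0):
            raise ValueError("target correlation must lie in (-1, 1)")
        cov = np.array([[1.0, grp.correlation], [grp.correlation, 1.0]])
        latent = rng.multivariate_normal([0.0, 0.0], cov, size=grp.n_samples)
        for i in range(grp.n_samples):
            sid = f"{grp.name}_e{i:04d}"
            m, t = latent[i]
            vals = [
                max(0.0, base_mean + base_sd * m + rng.normal(0.0, gene_noise_sd))
                for _ in complex_genes
            ]
            vals.append(max(0.0, base_mean + base_sd * t + rng.normal(0.0, gene_noise_sd)))
            cols[sid] = np.array(vals)
            labels[sid] = grp.name
    expr = pd.DataFrame(cols, index=[*complex_genes, target_gene])
    return expr, labels


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def write_vcf(calls: Sequence[SVCall], genome: GenomeRef, path) -> None:
    """Uncompressed VCF: symbolic ALT for canonical DEL/DUP/INV junction
    orientations, BND mate pairs otherwise."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">\n')
        fh.write('##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend">\n')
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write('##ALT=<ID=DUP,Description="Duplication">\n')
        fh.write('##ALT=<ID=INV,Description="Inversion">\n')
        for chrom in genome.chrom_names:
            fh.write(f"##contig=<ID={chrom},length={genome.chrom_lengths[chrom]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        rows = []
        for i, c in enumerate(calls):
            canonical = {"DEL": ("+", "-"), "DUP": ("-", "+"), "INV": ("+", "+")}.get(c.svtype)
            if c.intrachromosomal and canonical == c.orient_pair:
                ref = genome.fetch(c.b1.chrom, c.b1.pos, c.b1.pos + 1) or "N"
                rows.append(
                    (c.b1.chrom, c.b1.pos + 1, f"sv{i}", ref, f"<{c.svtype}>", ".", "PASS",
                     f"SVTYPE={c.svtype};END={c.b2.pos + 1}")
                )
            else:
                for this, mate, tag, mate_tag in (
                    (c.b1, c.b2, "a", "b"), (c.b2, c.b1, "b", "a"),
                ):
                    ref = genome.fetch(this.chrom, this.pos, this.pos + 1) or "N"
                    mstr = f"{mate.chrom}:{mate.pos + 1}"
                    bracket = "[" if mate.orient == "-" else "]"
                    alt = (
                        f"{ref}{bracket}{mstr}{bracket}"
                        if this.orient == "+"
                        else f"{bracket}{mstr}{bracket}{ref}"
                    )
                    rows.append(
                        (this.chrom, this.pos + 1, f"sv{i}{tag}", ref, alt, ".", "PASS",
                         f"SVTYPE={c.svtype};MATEID=sv{i}{mate_tag}")
                    )
        order = {c: i for i, c in enumerate(genome.chrom_names)}
        rows.sort(key=lambda r: (order.get(r[0], 99), r[1]))
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")


def write_cohort(
    scaffold: GenomeScaffold,
    cohort: SimulatedCohort,
    outdir,
    vcf: bool = True,
) -> None:
    """Emit the full synthetic data set in the formats the pipeline
    ingests (FASTA, BED, VCF/BEDPE, TSV) plus the truth ledger."""
    from pathlib import Path

    from . import cohort_io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort_io.write_fasta({c: s.decode() for c, s in scaffold.sequences.items()}, outdir / "genome.fa")
    with open(outdir / "genome.chrom.sizes", "w") as fh:
        for c, s in scaffold.sequences.items():
            fh.write(f"{c}\t{len(s)}\n")
    cohort_io.write_bed(scaffold.tads, outdir / "tads.bed", ["chrom", "start", "end", "tad_type"])
    cohort_io.write_bed(scaffold.boundaries, outdir / "boundaries.bed", ["chrom", "start", "end", "boundary_id"])
    cohort_io.write_bed(scaffold.genes, outdir / "genes.bed", ["chrom", "start", "end", "gene_symbol", "role"])
    cohort_io.write_bed(scaffold.fragile_sites, outdir / "fragile_sites.bed", ["chrom", "start", "end", "site_name"])
    cohort_io.write_sample_meta(cohort.meta, outdir / "sample_meta.tsv")
    cohort_io.write_chromothripsis_regions(cohort.regions, outdir / "chromothripsis_regions.tsv")
    ref = scaffold.ref
    calls_dir = outdir / "calls"
    calls_dir.mkdir(exist_ok=True)
    for sid, per_caller in cohort.calls.items():
        for caller, calls in per_caller.items():
            if vcf:
                write_vcf(calls, ref, calls_dir / f"{sid}.{caller}.vcf")
            else:
                cohort_io.write_bedpe(calls, calls_dir / f"{sid}.{caller}.bedpe")
    cohort_io.write_table(cohort.truth.svs, outdir / "truth_svs.tsv", kind="truth_svs")
    cohort_io.write_table(cohort.truth.samples, outdir / "truth_samples.tsv", kind="truth_samples")
    cohort_io.write_table(cohort.truth.false_positives, outdir / "truth_fps.tsv", kind="truth_fps")
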