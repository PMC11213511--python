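"""Chromothripsis event summaries and the chromosome-level enrichment
test (breakpoints reshuffled proportionally to chromosome length)."""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import ChromothripsisRegion, ConsensusSV, GenomeRef, SampleMeta


def event_summary(
    regions: Sequence[ChromothripsisRegion],
    meta: Sequence[SampleMeta] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize externally called chromothripsis events.

    Returns (events, samples): per-event distinct-chromosome counts with
    an interchromosomal flag (>=2 chromosomes), and per-sample
    has-chromothripsis / has-interchromosomal flags.  When metadata is
    given, every QC-passed sample appears in the sample table (flag False
    when it has no event) so subtype frequencies can be read off directly.
    """
    if meta is None and not regions:
        raise ValueError("no chromothripsis regions and no sample metadata")
    ev: dict[tuple[str, str], set[str]] = {}
    for r in regions:
        ev.setdefault((r.sample_id, r.event_id), set()).add(r.chrom)
    event_rows = [
        {
            "sample_id": s,
            "event_id": e,
            "n_chromosomes": len(chroms),
            "interchromosomal": len(chroms) >= 2,
        }
        for (s, e), chroms in sorted(ev.items())
    ]
    events = pd.DataFrame(event_rows, columns=["sample_id", "event_id", "n_chromosomes", "interchromosomal"])

    sample_ids = [m.sample_id for m in meta] if meta is not None else sorted({r.sample_id for r in regions})
    flags = events.groupby("sample_id").agg(
        n_events=("event_id", "size"), has_interchromosomal=("interchromosomal", "any")
    )
    sample_rows = []
    for sid in sample_ids:
        n = int(flags["n_events"].get(sid, 0))
        sample_rows.append(
            {
                "sample_id": sid,
                "has_chromothripsis": n > 0,
                "n_events": n,
                "has_interchromosomal": bool(flags["has_interchromosomal"].get(sid, False)),
            }
        )
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "has_chromothripsis", "n_events", "has_interchromosomal"])
    return events, samples


def chromothripsis_breakpoints(
    consensus: Iterable[ConsensusSV],
    regions: Sequence[ChromothripsisRegion],
) -> list[tuple[str, int]]:
    """Breakends of SVs associated with chromothripsis regions.

    An SV is chromothripsis-associated when at least one of its breakends
    falls inside one of its own sample's regions; both breakends of such
    an SV are returned (so interchromosomal SVs contribute to two
    chromosomes)."""
    by_sample: dict[str, list[ChromothripsisRegion]] = {}
    for r in regions:
        by_sample.setdefault(r.sample_id, []).append(r)

    def _inside(sample_id: str, chrom: str, pos: int) -> bool:
        return any(
            r.chrom == chrom and r.start <= pos < r.end for r in by_sample.get(sample_id, ())
        )

    out = []
    for sv in consensus:
        ends = [(sv.b1.chrom, sv.b1.pos), (sv.b2.chrom, sv.b2.pos)]
        if any(_inside(sv.sample_id, c, p) for c, p in ends):
            out.extend(ends)
    return out


def chrom_enrichment(
    breakpoints: Sequence[tuple[str, int]],
    genome: GenomeRef,
    n_perm: int = 1000,
    seed: int | None = None,
    smoothed: bool = False,
    exclude: Sequence[tuple[str, int, int]] | None = None,
    return_draws: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, np.ndarray]:
    """Permutation enrichment of chromothripsis breakpoints per chromosome.

    Each permutation reassigns every breakpoint to a chromosome with
    probability proportional to chromosome length (a multinomial draw);
    p(chrom) = #{permutations with draw >= observed} / n_perm.  With
    ``smoothed`` the add-one estimate (x+1)/(n+1) is reported instead.
    ``exclude`` intervals are subtracted from the chromosome weights.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not breakpoints:
        raise ValueError("breakpoint list is empty")
    chroms = list(genome.chrom_names)
    index = {c: i for i, c in enumerate(chroms)}
    observed = np.zeros(len(chroms), dtype=int)
    for chrom, _pos in breakpoints:
        if chrom not in index:
            raise KeyError(f"breakpoint chromosome {chrom!r} absent from genome")
        observed[index[chrom]] += 1
    weights = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    if exclude:
        for chrom, start, end in exclude:
            if chrom in index:
                weights[index[chrom]] -= max(0, end - start)
    weights = np.maximum(weights, 0.0)
    probs = weights / weights.sum()
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(len(breakpoints), probs, size=n_perm)
    ge = (draws >= observed[None, :]).sum(axis=0)
    p = (ge + 1) / (n_perm + 1) if smoothed else ge / n_perm
    df = pd.DataFrame(
        {
            "chrom": chroms,
            "observed_breakpoints": observed,
            "expected_breakpoints": len(breakpoints) * probs,
            "p_value": p,
        }
    )
    return (df, draws) if return_draws else df


def small_sv_in_regions(
    consensus: Iterable[ConsensusSV],
    regions: Sequence[ChromothripsisRegion],
    small_cutoff: int = 10_000,
) -> pd.DataFrame:
    """Fraction of small (size < cutoff) SVs lying inside chromothripsis
    regions, per sample and SV type.  An SV counts as inside only if both
    breakends fall in regions of its own sample."""
    by_sample: dict[str, list[ChromothripsisRegion]] = {}
    for r in regions:
        by_sample.setdefault(r.sample_id, []).append(r)

    def _inside(sample_id: str, chrom: str, pos: int) -> bool:
        return any(
            r.chrom == chrom and r.start <= pos < r.end for r in by_sample.get(sample_id, ())
        )

    counts: dict[tuple[str, str], list[int]] = {}
    for sv in consensus:
        if sv.size is None or sv.size >= small_cutoff:
            continue
        key = (sv.sample_id, sv.svtype)
        n_small, n_inside = counts.setdefault(key, [0, 0])
        counts[key][0] = n_small + 1
        if _inside(sv.sample_id, sv.b1.chrom, sv.b1.pos) and _inside(sv.sample_id, sv.b2.chrom, sv.b2.pos):
            counts[key][1] = n_inside + 1
    rows = [
        {
            "sample_id": s,
            "svtype": t,
            "n_small": ns,
            "n_inside": ni,
            "frac_inside": ni / ns if ns else float("nan"),
        }
        for (s, t), (ns, ni) in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["sample_id", "svtype", "n_small", "n_inside", "frac_inside"])
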