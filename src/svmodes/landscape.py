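"""Cohort SV-landscape statistics: per-sample burden, group comparisons
(Mann-Whitney / Kolmogorov-Smirnov with BH adjustment), and size spectra.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import ConsensusSV, SampleMeta

logger = logging.getLogger(__name__)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney test.

    Exact null enumeration when both groups have n < 50 and the pooled
    data is tie-free (mirroring R's wilcox.test); otherwise the normal
    approximation with tie-corrected variance and continuity correction.
    Returns (U statistic for the first group, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and n1 < 50 and n2 < 50:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue)
    ranks = stats.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    sigma2 = (n1 * n2 / 12.0) * ((n + 1) - tie_term / (n * (n - 1)))
    diff = u1 - mu
    if sigma2 <= 0:
        return u1, 1.0
    z = (diff - np.sign(diff) * 0.5) / np.sqrt(sigma2)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return u1, float(p)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    m = len(pv)
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[mask] = res
    return out


def burden_table(consensus: Iterable[ConsensusSV], meta: Sequence[SampleMeta]) -> pd.DataFrame:
    """Exact per-sample SV class counts; QC-passed samples without SVs
    are retained as all-zero rows.  A consensus sample missing from the
    metadata is an error."""
    known = {m.sample_id for m in meta}
    rows = {
        m.sample_id: {"sample_id": m.sample_id, "DEL": 0, "DUP": 0, "INV": 0, "TRA": 0,
                      "intra_tra": 0, "inter_tra": 0}
        for m in meta
    }
    unknown = set()
    for r in consensus:
        if r.sample_id not in known:
            unknown.add(r.sample_id)
            continue
        row = rows[r.sample_id]
        row[r.svtype] += 1
        if r.svtype == "TRA":
            row["intra_tra" if r.intrachromosomal else "inter_tra"] += 1
    if unknown:
        raise ValueError(f"consensus samples absent from metadata: {sorted(unknown)}")
    df = pd.DataFrame(list(rows.values()))
    df["total"] = df[["DEL", "DUP", "INV", "TRA"]].sum(axis=1)
    return df[["sample_id", "DEL", "DUP", "INV", "TRA", "total", "intra_tra", "inter_tra"]]


def compare_groups(
    values: Mapping[str, float],
    grouping: Mapping[str, str],
    method: str = "mann-whitney",
    fdr: str = "bh",
) -> pd.DataFrame:
    """All pairwise two-sided group comparisons of a per-sample quantity.

    ``values`` maps sample -> value and ``grouping`` maps sample -> group
    label.  BH adjustment is applied across the comparisons of this one
    invocation when ``fdr="bh"``.  Empty groups are skipped and flagged.
    """
    if method not in ("mann-whitney", "ks"):
        raise ValueError(f"unknown method {method!r}")
    by_group: dict[str, list[float]] = {}
    for sample, g in grouping.items():
        by_group.setdefault(g, [])
        if sample in values:
            by_group[g].append(float(values[sample]))
    groups = sorted(by_group)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for g1, g2 in itertools.combinations(groups, 2):
        x, y = by_group[g1], by_group[g2]
        if not x or not y:
            logger.warning("comparison %s vs %s skipped: empty group", g1, g2)
            rows.append({"group1": g1, "group2": g2, "n1": len(x), "n2": len(y),
                         "statistic": np.nan, "p": np.nan, "skipped": True})
            continue
        if method == "mann-whitney":
            stat, p = mann_whitney(x, y)
        else:
            res = stats.ks_2samp(x, y, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append({"group1": g1, "group2": g2, "n1": len(x), "n2": len(y),
                     "statistic": stat, "p": p, "skipped": False})
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p"].to_numpy()) if fdr == "bh" else df["p"]
    return df


def size_spectrum(
    consensus: Iterable[ConsensusSV],
    group_by: Mapping[str, str],
    small_cutoff: int = 10_000,
    svtypes: tuple[str, ...] = ("DEL", "DUP", "INV", "TRA"),
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Per-group empirical size distributions on log2 scale.

    Only intrachromosomal records contribute (TRA with undefined size is
    excluded).  Returns a summary table with the fraction of events below
    ``small_cutoff`` per group, and the raw log2 sizes per group.
    """
    sizes: dict[str, list[int]] = {}
    for r in consensus:
        if not r.intrachromosomal or r.svtype not in svtypes:
            continue
        g = group_by.get(r.sample_id)
        if g is None:
            continue
        sizes.setdefault(g, []).append(r.size)
    summary = []
    log_sizes: dict[str, np.ndarray] = {}
    for g in sorted(sizes):
        arr = np.asarray(sizes[g], dtype=float)
        log_sizes[g] = np.log2(np.maximum(arr, 1.0))
        summary.append({
            "group": g,
            "n": len(arr),
            "frac_small": float(np.mean(arr < small_cutoff)) if len(arr) else np.nan,
            "median_size": float(np.median(arr)) if len(arr) else np.nan,
        })
    return pd.DataFrame(summary, columns=["group", "n", "frac_small", "median_size"]), log_sizes
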