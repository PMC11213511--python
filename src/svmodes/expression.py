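"""Gene-complex expression coupling: geometric-mean complex scores,
Fisher z comparison of group correlations, downsampling analysis, and
SV-versus-expression z-score percentiles."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .landscape import mann_whitney

logger = logging.getLogger(__name__)


def complex_score(expr: pd.DataFrame, genes: Iterable[str]) -> pd.Series:
    """Per-sample geometric mean of a gene set (genes x samples matrix).

    Values are offset by +1 before the log-mean and -1 after, so zero
    expression is tolerated and the score is never negative.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing}")
    sub = expr.loc[genes].astype(float)
    if (sub < 0).any().any():
        raise ValueError("expression matrix contains negative values")
    return np.exp(np.log1p(sub).mean(axis=0)) - 1.0


@dataclass
class CorrelationComparison:
    r1: float
    r2: float
    n1: int
    n2: int
    z_stat: float
    p_two_sided: float
    downsample_p: float | None = None


def fisher_z_test(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Fisher z-transformation comparison of two independent Pearson
    correlations; returns (z, two-sided normal p)."""
    if n1 < 4 or n2 < 4:
        raise ValueError("need at least 4 samples per group")
    if abs(r1) >= 1.0 or abs(r2) >= 1.0:
        logger.warning("|r| = 1 gives an infinite z-transform")
        z = np.inf if abs(r1) >= 1.0 and r1 > r2 else -np.inf
        return float(z), 0.0
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(z), float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def compare_correlations(
    x: Mapping[str, float],
    y: Mapping[str, float],
    groups: Mapping[str, str],
    group1: str | None = None,
    group2: str | None = None,
) -> CorrelationComparison:
    """Pearson correlation of x vs y within two groups, compared via the
    Fisher z-transformation (two-sided)."""
    labels = sorted(set(groups.values()))
    if group1 is None or group2 is None:
        if len(labels) != 2:
            raise ValueError("grouping must have exactly two labels or name them explicitly")
        group1, group2 = labels
    samples = [s for s in groups if s in x and s in y]
    xv = {g: [x[s] for s in samples if groups[s] == g] for g in (group1, group2)}
    yv = {g: [y[s] for s in samples if groups[s] == g] for g in (group1, group2)}
    n1, n2 = len(xv[group1]), len(xv[group2])
    r1 = float(stats.pearsonr(xv[group1], yv[group1]).statistic)
    r2 = float(stats.pearsonr(xv[group2], yv[group2]).statistic)
    z, p = fisher_z_test(r1, n1, r2, n2)
    return CorrelationComparison(r1=r1, r2=r2, n1=n1, n2=n2, z_stat=z, p_two_sided=p)


def _pearson_rows(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two equally-shaped 2-D arrays."""
    xc = xs - xs.mean(axis=1, keepdims=True)
    yc = ys - ys.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def downsample_correlation(
    x: Mapping[str, float],
    y: Mapping[str, float],
    small_group: Sequence[str],
    large_group: Sequence[str],
    n_draws: int = 10_000,
    seed: int | None = None,
) -> float:
    """Fraction of size-matched subsamples of the large group whose
    Pearson r strictly exceeds the small group's observed r."""
    small = [s for s in small_group if s in x and s in y]
    large = [s for s in large_group if s in x and s in y]
    if len(large) <= len(small):
        raise ValueError("large group must be strictly larger than small group")
    r_small = float(stats.pearsonr([x[s] for s in small], [y[s] for s in small]).statistic)
    lx = np.array([x[s] for s in large])
    ly = np.array([y[s] for s in large])
    rng = np.random.default_rng(seed)
    k = len(small)
    idx = np.argsort(rng.random((n_draws, len(large))), axis=1)[:, :k]
    rs = _pearson_rows(lx[idx], ly[idx])
    return float(np.mean(rs > r_small))


def sv_expression_percentile(
    expr: pd.DataFrame,
    sv_status: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Per-gene z-scores, percentile ranks of SV-bearing samples, and a
    pooled Mann-Whitney test on the aggregated z-scores.

    ``sv_status`` is a boolean genes x samples frame aligned with
    ``expr``.  Zero-variance genes are skipped with a log message.
    Percentile = average rank / n * 100 (ties get average ranks).
    """
    common_genes = [g for g in expr.index if g in sv_status.index]
    common_samples = [s for s in expr.columns if s in sv_status.columns]
    if len(common_samples) < 2:
        raise ValueError("need at least 2 shared samples")
    z_rows, pct_rows = {}, []
    pooled_sv, pooled_other = [], []
    for g in common_genes:
        vals = expr.loc[g, common_samples].astype(float).to_numpy()
        if np.std(vals, ddof=1) == 0:
            logger.warning("gene %s has zero expression variance; skipped", g)
            continue
        z = (vals - vals.mean()) / vals.std(ddof=1)
        z_rows[g] = z
        ranks = stats.rankdata(vals)
        flags = sv_status.loc[g, common_samples].astype(bool).to_numpy()
        for i, s in enumerate(common_samples):
            if flags[i]:
                pct_rows.append({"gene": g, "sample_id": s, "z": z[i],
                                 "percentile": 100.0 * ranks[i] / len(vals)})
        pooled_sv.extend(z[flags])
        pooled_other.extend(z[~flags])
    zdf = pd.DataFrame.from_dict(z_rows, orient="index", columns=common_samples)
    pct = pd.DataFrame(pct_rows, columns=["gene", "sample_id", "z", "percentile"])
    if pooled_sv and pooled_other:
        _, pooled_p = mann_whitney(pooled_sv, pooled_other)
    else:
        pooled_p = float("nan")
    return zdf, pct, pooled_p
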