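"""Exact 2x2 inference and subtype/signature enrichment.

``fisher_exact`` reports the conditional maximum-likelihood odds ratio of
the noncentral hypergeometric likelihood (the estimator printed by R's
``fisher.test``; for the 5/20-vs-5/155 style tables the sample
cross-product ratio differs), an exact conditional confidence interval by
one-sided test inversion, and the two-sided probability-method p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp

from .landscape import bh_adjust
from .model import ConsensusSV, GeneAnnotation

logger = logging.getLogger(__name__)

_REL_TOL = 1.0 + 1e-7  # relative slack when comparing table probabilities


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows = group / non-group, columns = feature+ / feature-."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def margins_positive(self) -> bool:
        return (
            self.a + self.b > 0
            and self.c + self.d > 0
            and self.a + self.c > 0
            and self.b + self.d > 0
        )


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float  # conditional MLE; may be 0 or +inf
    ci_low: float
    ci_high: float
    p_two_sided: float


class _CondDist:
    """Conditional distribution of the (1,1) cell given both margins."""

    def __init__(self, t: ContingencyTable):
        n1, n2, m1 = t.a + t.b, t.c + t.d, t.a + t.c
        self.lo = max(0, m1 - n2)
        self.hi = min(m1, n1)
        self.support = np.arange(self.lo, self.hi + 1)
        x = self.support
        self.logw = (
            gammaln(n1 + 1) - gammaln(x + 1) - gammaln(n1 - x + 1)
            + gammaln(n2 + 1) - gammaln(m1 - x + 1) - gammaln(n2 - m1 + x + 1)
        )

    def logpmf(self, log_psi: float) -> np.ndarray:
        lp = self.logw + self.support * log_psi
        return lp - logsumexp(lp)

    def pmf(self, log_psi: float) -> np.ndarray:
        return np.exp(self.logpmf(log_psi))

    def mean(self, log_psi: float) -> float:
        return float(np.sum(self.support * self.pmf(log_psi)))

    def cdf_at(self, a: int, log_psi: float) -> float:
        p = self.pmf(log_psi)
        return float(p[self.support <= a].sum())

    def sf_at(self, a: int, log_psi: float) -> float:
        p = self.pmf(log_psi)
        return float(p[self.support >= a].sum())


def _solve_monotone(f, target: float, increasing: bool) -> float:
    """Root of f(log_psi) = target for a monotone f, with an expanding
    bracket.  Returns the log of the solution."""

    def g(lp):
        v = f(lp) - target
        return v if increasing else -v

    lo, hi = -1.0, 1.0
    for _ in range(80):
        if g(lo) <= 0:
            break
        lo *= 2
    for _ in range(80):
        if g(hi) >= 0:
            break
        hi *= 2
    return brentq(g, lo, hi, xtol=1e-12, rtol=1e-14, maxiter=200)


def fisher_exact(t: ContingencyTable, conf_level: float = 0.95) -> FisherResult:
    """Exact conditional inference for a 2x2 table.

    * odds ratio: solves E[X | psi] = a (conditional MLE); 0 when a is at
      the lower support end, +inf when at the upper end.
    * CI: inverts one-sided exact tests at (1 - conf_level)/2 per side.
    * p: two-sided probability method — the sum of conditional
      probabilities (at psi = 1) of all tables no more probable than the
      observed one.
    """
    if not t.margins_positive:
        raise ValueError("all four table margins must be positive")
    dist = _CondDist(t)
    a = t.a
    alpha = (1.0 - conf_level) / 2.0

    pmf1 = dist.pmf(0.0)
    p_obs = pmf1[dist.support == a][0]
    p_two = float(pmf1[pmf1 <= p_obs * _REL_TOL].sum())
    p_two = min(1.0, p_two)

    if dist.lo == dist.hi:
        return FisherResult(1.0, 0.0, np.inf, 1.0)

    if a == dist.lo:
        orr = 0.0
    elif a == dist.hi:
        orr = np.inf
    else:
        orr = float(np.exp(_solve_monotone(dist.mean, a, increasing=True)))

    if a == dist.lo:
        ci_low = 0.0
    else:
        # P(X >= a | psi) increases with psi; the lower bound solves it = alpha
        ci_low = float(np.exp(_solve_monotone(lambda lp: dist.sf_at(a, lp), alpha, increasing=True)))
    if a == dist.hi:
        ci_high = np.inf
    else:
        ci_high = float(np.exp(_solve_monotone(lambda lp: dist.cdf_at(a, lp), alpha, increasing=False)))
    return FisherResult(orr, ci_low, ci_high, p_two)


# ---------------------------------------------------------------------------
# Gene-level SV enrichment
# ---------------------------------------------------------------------------

GENE_FILTERS = ("any", "non-duplication", "complex-only")


def sv_overlaps_gene(sv: ConsensusSV, gene: GeneAnnotation) -> bool:
    """Intrachromosomal SVs alter a gene when their breakend span overlaps
    it; interchromosomal SVs when a breakend falls inside it."""
    if sv.intrachromosomal:
        chrom, start, end = sv.span()
        return chrom == gene.chrom and start < gene.end and gene.start < max(end, start + 1)
    return any(
        b.chrom == gene.chrom and gene.start <= b.pos < gene.end for b in (sv.b1, sv.b2)
    )


def gene_alteration_matrix(
    consensus: Iterable[ConsensusSV],
    genes: Sequence[GeneAnnotation],
    samples: Sequence[str],
    sv_filter: str = "any",
    complex_svs: frozenset | set | None = None,
) -> pd.DataFrame:
    """Boolean genes x samples matrix of per-sample gene alteration."""
    if sv_filter not in GENE_FILTERS:
        raise ValueError(f"unknown filter {sv_filter!r}")
    complex_svs = complex_svs or frozenset()
    mat = pd.DataFrame(False, index=[g.gene_symbol for g in genes], columns=list(samples))
    for sv in consensus:
        if sv_filter == "non-duplication" and sv.svtype == "DUP":
            continue
        if sv_filter == "complex-only" and sv not in complex_svs:
            continue
        if sv.sample_id not in mat.columns:
            continue
        for g in genes:
            if sv_overlaps_gene(sv, g):
                mat.loc[g.gene_symbol, sv.sample_id] = True
    return mat


def gene_sv_enrichment(
    consensus: Iterable[ConsensusSV],
    genes: Sequence[GeneAnnotation],
    grouping: Mapping[str, str],
    sv_filter: str = "any",
    complex_svs: frozenset | set | None = None,
    conf_level: float = 0.95,
) -> pd.DataFrame:
    """Per-gene, per-group exact enrichment of altered samples (group vs
    rest), BH-adjusted across all (gene, group) comparisons."""
    samples = sorted(grouping)
    mat = gene_alteration_matrix(consensus, genes, samples, sv_filter, complex_svs)
    group_labels = sorted(set(grouping.values()))
    rows = []
    for gene in mat.index:
        altered = mat.loc[gene]
        for g in group_labels:
            in_group = np.array([grouping[s] == g for s in samples])
            alt = altered.to_numpy()
            t = ContingencyTable(
                int((alt & in_group).sum()),
                int((~alt & in_group).sum()),
                int((alt & ~in_group).sum()),
                int((~alt & ~in_group).sum()),
            )
            if not t.margins_positive:
                rows.append({"gene": gene, "group": g, "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                             "odds_ratio": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan})
                continue
            res = fisher_exact(t, conf_level)
            rows.append({"gene": gene, "group": g, "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                         "odds_ratio": res.odds_ratio, "ci_low": res.ci_low,
                         "ci_high": res.ci_high, "p": res.p_two_sided})
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# Covariate-adjusted burden regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    coefficients: pd.DataFrame  # term, coef, se, t, p
    n_used: int
    dropped_samples: list[str]
    flags: list[str]

    def coef(self, term: str) -> pd.Series:
        match = self.coefficients[self.coefficients["term"] == term]
        if match.empty:
            raise KeyError(term)
        return match.iloc[0]


def burden_regression(
    counts: Mapping[str, float],
    signature_flags: Mapping[str, bool],
    covariates: pd.DataFrame,
    family: str = "ols",
) -> RegressionResult:
    """Linear model of log2(count + 1) on signature presence with
    categorical stage/genomic-subtype and numeric coverage/purity
    covariates.  Samples with missing values are dropped and reported;
    collinear or zero-variance covariates are flagged (their coefficients
    are not interpretable).  ``family="negbin"`` fits a negative binomial
    on the raw counts instead.
    """
    import statsmodels.api as sm

    required = ["stage", "genomic_subtype", "coverage", "purity"]
    missing_cols = [c for c in required if c not in covariates.columns]
    if missing_cols:
        raise ValueError(f"covariates missing columns: {missing_cols}")

    df = covariates.copy()
    df["count"] = pd.Series(dict(counts))
    df["signature"] = pd.Series({s: bool(v) for s, v in signature_flags.items()})
    complete = df.dropna(subset=required + ["count", "signature"])
    dropped = sorted(set(df.index) - set(complete.index))
    if dropped:
        logger.warning("burden_regression: dropped %d samples with missing values", len(dropped))
    if len(complete) < len(required) + 2:
        raise ValueError("too few complete samples for regression")

    flags = []
    X_parts = [pd.Series(1.0, index=complete.index, name="Intercept"),
               complete["signature"].astype(float).rename("signature")]
    for col in ("stage", "genomic_subtype"):
        dummies = pd.get_dummies(complete[col].astype(str), prefix=col, drop_first=True, dtype=float)
        X_parts.extend(dummies[c] for c in dummies.columns)
    for col in ("coverage", "purity"):
        s = complete[col].astype(float)
        if s.nunique() <= 1:
            flags.append(f"zero-variance covariate: {col}")
            continue
        X_parts.append(s.rename(col))
    X = pd.concat(X_parts, axis=1)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        flags.append("collinear design matrix; coefficients undefined")

    if family == "negbin":
        model = sm.NegativeBinomial(complete["count"].astype(float), X)
        fit = model.fit(disp=0)
    elif family == "ols":
        y = np.log2(complete["count"].astype(float) + 1.0)
        fit = sm.OLS(y, X).fit()
    else:
        raise ValueError(f"unknown family {family!r}")

    coefs = pd.DataFrame(
        {
            "term": fit.params.index,
            "coef": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "stat": fit.tvalues.to_numpy(),
            "p": fit.pvalues.to_numpy(),
        }
    )
    return RegressionResult(coefs, len(complete), dropped, flags)
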