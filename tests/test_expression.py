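import numpy as np
import pandas as pd
import pytest
from scipy import stats

from svmodes.expression import (
    compare_correlations,
    complex_score,
    downsample_correlation,
    fisher_z_test,
    sv_expression_percentile,
)
from svmodes.simulate import ExpressionGroup, simulate_expression


def matrix(values: dict[str, list[float]], samples=None) -> pd.DataFrame:
    df = pd.DataFrame(values).T
    df.columns = samples or [f"s{i}" for i in range(df.shape[1])]
    return df


class TestComplexScore:
    def test_geometric_mean_2_4_8(self):
        # plain geometric mean of (2,4,8) is 4; the +1/-1 offset variant
        # gives exp(mean(log(3,5,9))) - 1
        expr = matrix({"A": [2.0], "B": [4.0], "C": [8.0]})
        score = complex_score(expr, ["A", "B", "C"])
        expected = np.exp(np.mean(np.log([3, 5, 9]))) - 1
        assert score.iloc[0] == pytest.approx(expected)

    def test_identity_on_equal_values(self):
        expr = matrix({"A": [7.0, 3.0], "B": [7.0, 3.0]})
        score = complex_score(expr, ["A", "B"])
        assert score.to_numpy() == pytest.approx([7.0, 3.0])

    def test_zero_values_never_negative(self):
        expr = matrix({"A": [0.0], "B": [0.0], "C": [8.0]})
        score = complex_score(expr, ["A", "B", "C"])
        assert score.iloc[0] == pytest.approx(np.exp(np.log(9) / 3) - 1)
        assert score.iloc[0] >= 0

    def test_log_score_equals_mean_log_for_positive(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(1, 100, size=(3, 20))
        expr = matrix({g: vals[i].tolist() for i, g in enumerate("ABC")})
        score = complex_score(expr, ["A", "B", "C"])
        assert np.log(score + 1).to_numpy() == pytest.approx(
            np.log(vals + 1).mean(axis=0), abs=1e-10
        )

    def test_missing_gene_named_in_error(self):
        expr = matrix({"A": [1.0]})
        with pytest.raises(KeyError, match="MRE11"):
            complex_score(expr, ["A", "MRE11"])


class TestFisherZ:
    def test_equal_correlations_p_one(self):
        z, p = fisher_z_test(0.5, 50, 0.5, 80)
        assert z == 0.0 and p == 1.0

    def test_closed_form_example(self):
        z, p = fisher_z_test(0.5, 103, 0.0, 103)
        assert z == pytest.approx(np.arctanh(0.5) * np.sqrt(50), rel=1e-12)
        assert p == pytest.approx(2 * stats.norm.sf(np.arctanh(0.5) * np.sqrt(50)), rel=1e-12)
        assert p == pytest.approx(1.0e-4, rel=0.1)

    def test_perfect_correlation_flagged_infinite(self):
        z, p = fisher_z_test(1.0, 50, 0.5, 50)
        assert np.isinf(z) and p == 0.0

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            fisher_z_test(0.5, 3, 0.2, 50)

    def test_rejection_rate_tracks_analytic_power(self):
        # true r 0.82 vs 0.69 at n 20 vs 140: analytic power at alpha=0.05
        mean_z = (np.arctanh(0.82) - np.arctanh(0.69)) / np.sqrt(1 / 17 + 1 / 137)
        analytic = stats.norm.sf(1.96 - mean_z) + stats.norm.cdf(-1.96 - mean_z)
        rng = np.random.default_rng(8)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            g1 = rng.multivariate_normal([0, 0], [[1, 0.82], [0.82, 1]], size=20)
            g2 = rng.multivariate_normal([0, 0], [[1, 0.69], [0.69, 1]], size=140)
            r1 = stats.pearsonr(g1[:, 0], g1[:, 1]).statistic
            r2 = stats.pearsonr(g2[:, 0], g2[:, 1]).statistic
            _, p = fisher_z_test(r1, 20, r2, 140)
            rejections += p < 0.05
        # the z approximation is slightly anti-conservative at n1=20, so
        # the empirical rate runs a little above the analytic value
        assert rejections / n_rep == pytest.approx(analytic, abs=0.10)

    def test_p_matches_permutation_oracle(self):
        rng = np.random.default_rng(3)
        n = 30
        xy = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=2 * n)
        labels = np.array([0] * n + [1] * n)

        def z_of(lab):
            r = [stats.pearsonr(xy[lab == g, 0], xy[lab == g, 1]).statistic for g in (0, 1)]
            return (np.arctanh(r[0]) - np.arctanh(r[1])) / np.sqrt(2 / (n - 3))

        z_obs = z_of(labels)
        perm = 0
        n_perm = 400
        for _ in range(n_perm):
            perm += abs(z_of(rng.permutation(labels))) >= abs(z_obs)
        p_perm = perm / n_perm
        _, p = fisher_z_test(*[
            stats.pearsonr(xy[:n, 0], xy[:n, 1]).statistic, n,
        ], *[
            stats.pearsonr(xy[n:, 0], xy[n:, 1]).statistic, n,
        ])
        assert p == pytest.approx(p_perm, abs=3 * np.sqrt(p_perm * (1 - p_perm) / n_perm) + 0.02)


class TestCompareCorrelations:
    def test_group_assignment(self):
        rng = np.random.default_rng(5)
        samples = [f"s{i}" for i in range(60)]
        groups = {s: ("a" if i < 30 else "b") for i, s in enumerate(samples)}
        x = {s: float(v) for s, v in zip(samples, rng.normal(size=60))}
        y = {s: x[s] * 0.5 + float(v) for s, v in zip(samples, rng.normal(size=60))}
        comp = compare_correlations(x, y, groups)
        assert comp.n1 == comp.n2 == 30
        assert -1 <= comp.r1 <= 1 and -1 <= comp.r2 <= 1


class TestDownsample:
    def _data(self, rng, r_small, r_large, n_small=20, n_large=140):
        x, y, small, large = {}, {}, [], []
        g1 = rng.multivariate_normal([0, 0], [[1, r_small], [r_small, 1]], size=n_small)
        g2 = rng.multivariate_normal([0, 0], [[1, r_large], [r_large, 1]], size=n_large)
        for i in range(n_small):
            s = f"sm{i}"
            x[s], y[s] = g1[i]
            small.append(s)
        for i in range(n_large):
            s = f"lg{i}"
            x[s], y[s] = g2[i]
            large.append(s)
        return x, y, small, large

    def test_single_draw_is_zero_or_one(self):
        rng = np.random.default_rng(0)
        x, y, small, large = self._data(rng, 0.5, 0.5)
        p = downsample_correlation(x, y, small, large, n_draws=1, seed=1)
        assert p in (0.0, 1.0)

    def test_identical_distribution_centered(self):
        rng = np.random.default_rng(1)
        ps = []
        for seed in range(40):
            x, y, small, large = self._data(np.random.default_rng(seed), 0.6, 0.6)
            ps.append(downsample_correlation(x, y, small, large, n_draws=300, seed=seed))
        assert np.mean(ps) == pytest.approx(0.5, abs=0.08)

    def test_higher_small_group_correlation_low_tail(self):
        # true r 0.82 (n=20) vs 0.69 (n=140): the mean downsample p over
        # replicates sits near 0.15, far below the 0.5 of the no-difference
        # case; assert it is clearly in the low tail
        from svmodes.expression import complex_score
        from svmodes.simulate import ExpressionGroup, simulate_expression

        ps = []
        for seed in range(50):
            expr, labels = simulate_expression(
                [ExpressionGroup("small", 20, 0.82), ExpressionGroup("large", 140, 0.69)], seed=seed
            )
            score = complex_score(expr, ["MRE11", "NBN", "RAD50"]).to_dict()
            atm = expr.loc["ATM"].to_dict()
            small = [s for s, g in labels.items() if g == "small"]
            large = [s for s, g in labels.items() if g == "large"]
            ps.append(downsample_correlation(score, atm, small, large, n_draws=400, seed=seed))
        assert np.mean(ps) < 0.2
        assert np.median(ps) < 0.15

    def test_large_group_must_be_larger(self):
        rng = np.random.default_rng(2)
        x, y, small, large = self._data(rng, 0.5, 0.5, n_small=30, n_large=30)
        with pytest.raises(ValueError):
            downsample_correlation(x, y, small, large, n_draws=10, seed=0)

    def test_seed_determinism(self):
        rng = np.random.default_rng(3)
        x, y, small, large = self._data(rng, 0.5, 0.5)
        a = downsample_correlation(x, y, small, large, n_draws=500, seed=11)
        b = downsample_correlation(x, y, small, large, n_draws=500, seed=11)
        assert a == b


class TestSvExpressionPercentile:
    def test_max_expresser_percentile_100(self):
        samples = [f"s{i}" for i in range(100)]
        expr = pd.DataFrame([np.arange(100.0)], index=["G1"], columns=samples)
        status = pd.DataFrame([[False] * 99 + [True]], index=["G1"], columns=samples)
        _, pct, _ = sv_expression_percentile(expr, status)
        assert pct.iloc[0]["percentile"] == 100.0

    def test_zero_variance_gene_skipped(self):
        samples = ["s1", "s2", "s3"]
        expr = pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]], index=["G0", "G1"], columns=samples)
        status = pd.DataFrame(True, index=["G0", "G1"], columns=samples)
        zdf, _, _ = sv_expression_percentile(expr, status)
        assert list(zdf.index) == ["G1"]

    def test_null_pooled_p_uniform(self):
        ps = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            expr = pd.DataFrame(rng.normal(100, 10, size=(10, 50)),
                                index=[f"G{i}" for i in range(10)],
                                columns=[f"s{i}" for i in range(50)])
            status = pd.DataFrame(rng.random((10, 50)) < 0.2,
                                  index=expr.index, columns=expr.columns)
            _, _, p = sv_expression_percentile(expr, status)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(100, 10, size=(10, 50)),
                            index=[f"G{i}" for i in range(10)],
                            columns=[f"s{i}" for i in range(50)])
        status = pd.DataFrame(rng.random((10, 50)) < 0.15,
                              index=expr.index, columns=expr.columns)
        expr = expr + status * 20.0  # +2 SD shift in SV-bearing samples
        _, _, p = sv_expression_percentile(expr, status)
        assert p < 0.01


class TestSimulatedExpression:
    def test_zero_correlation_within_sampling_error(self):
        expr, labels = simulate_expression([ExpressionGroup("g", 400, 0.0)], seed=4)
        score = complex_score(expr, ["MRE11", "NBN", "RAD50"])
        r = stats.pearsonr(score, expr.loc["ATM"]).statistic
        assert abs(r) < 3 / np.sqrt(400)

    def test_high_correlation_recovered(self):
        expr, labels = simulate_expression([ExpressionGroup("g", 10_000, 0.82)], seed=5)
        score = complex_score(expr, ["MRE11", "NBN", "RAD50"])
        r = stats.pearsonr(score, expr.loc["ATM"]).statistic
        assert r == pytest.approx(0.82, abs=0.02)

    def test_seed_determinism(self):
        a, _ = simulate_expression([ExpressionGroup("g", 50, 0.5)], seed=6)
        b, _ = simulate_expression([ExpressionGroup("g", 50, 0.5)], seed=6)
        assert a.equals(b)

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ValueError):
            simulate_expression([ExpressionGroup("g", 10, 1.0)], seed=0)
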