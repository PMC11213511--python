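import numpy as np
import pytest
from scipy import stats

from svmodes.model import (
    Breakend,
    ChromothripsisRegion,
    ConsensusSV,
    FragileSite,
    GeneAnnotation,
    GenomeRef,
    TADBoundary,
    TADRegion,
)
from svmodes.tads import (
    basv_burden_correlation,
    basv_permutation,
    count_boundary_affecting,
    detect_ba_svs,
    recurrence_and_adjacency,
)

from conftest import make_consensus


def simple_scaffold():
    boundary = TADBoundary("chr1", 500, 600, "b0")
    tads = [TADRegion("chr1", 0, 500, "active"), TADRegion("chr1", 600, 1200, "repressed")]
    genes = [
        GeneAnnotation("ONC1", "chr1", 100, 200, "oncogene"),
        GeneAnnotation("TSG1", "chr1", 700, 900, "tumor-suppressor"),
    ]
    return [boundary], tads, genes


class TestDetectBaSvs:
    def test_full_containment_required(self):
        bounds, tads, genes = simple_scaffold()
        hit = make_consensus(pos1=400, pos2=700)
        miss = make_consensus(pos1=550, pos2=700)
        recs = detect_ba_svs([hit, miss], bounds, tads, genes)
        assert len(recs) == 1
        assert recs[0].sv is hit
        assert recs[0].boundary_id == "b0"

    def test_size_cutoff_strict(self):
        bounds = [TADBoundary("chr1", 500_000, 505_000, "b0")]
        at_limit = make_consensus(pos1=100_000, pos2=2_100_000)
        assert at_limit.size == 2_000_000
        assert detect_ba_svs([at_limit], bounds) == []
        below = make_consensus(pos1=100_001, pos2=2_100_000)
        assert len(detect_ba_svs([below], bounds)) == 1

    def test_adjacent_tads_and_genes(self):
        bounds, tads, genes = simple_scaffold()
        (rec,) = detect_ba_svs([make_consensus(pos1=400, pos2=700)], bounds, tads, genes)
        assert rec.adjacent_tad_types == ("active", "repressed")
        assert {g.gene_symbol for g in rec.adjacent_genes} == {"ONC1", "TSG1"}

    def test_missing_adjacency_recorded_as_none(self):
        bounds, _, _ = simple_scaffold()
        tads = [TADRegion("chr1", 0, 500, "active")]  # no right-hand TAD
        (rec,) = detect_ba_svs([make_consensus(pos1=400, pos2=700)], bounds, tads)
        assert rec.adjacent_tad_types == ("active", None)

    def test_complex_via_chromothripsis_region(self):
        bounds, tads, genes = simple_scaffold()
        ct = [ChromothripsisRegion("s1", "e1", "chr1", 0, 1000)]
        (rec,) = detect_ba_svs([make_consensus(pos1=400, pos2=700)], bounds, tads, genes, ct)
        assert rec.event_class == "complex"

    def test_complex_via_overlapping_concomitant_sv(self):
        bounds, tads, genes = simple_scaffold()
        sv = make_consensus(pos1=400, pos2=700)
        other = make_consensus(pos1=650, pos2=9_000, svtype="DUP", o1="-", o2="+")
        (rec,) = detect_ba_svs([sv, other], bounds, tads, genes)
        assert rec.event_class == "complex"

    def test_isolated_sv_keeps_own_class(self):
        bounds, tads, genes = simple_scaffold()
        (rec,) = detect_ba_svs([make_consensus(pos1=400, pos2=700)], bounds, tads, genes)
        assert rec.event_class == "DEL"

    def test_matches_all_pairs_interval_oracle(self, rng):
        bounds = [
            TADBoundary("chr1", int(s), int(s) + 50, f"b{i}")
            for i, s in enumerate(range(100, 20_000, 400))
        ]
        for _ in range(300):
            p1 = int(rng.integers(0, 20_000))
            p2 = p1 + int(rng.integers(40, 3_000))
            sv = make_consensus(pos1=p1, pos2=p2)
            expected = {b.boundary_id for b in bounds if p1 <= b.start and b.end <= p2}
            got = {r.boundary_id for r in detect_ba_svs([sv], bounds)}
            assert got == expected


class TestBasvPermutation:
    def test_boundaries_everywhere_p_one(self):
        g = GenomeRef(["chr1"], {"chr1": 10_000})
        bounds = [TADBoundary("chr1", i, i + 1, f"b{i}") for i in range(0, 10_000, 2)]
        svs = [make_consensus(pos1=100 * i, pos2=100 * i + 50) for i in range(5)]
        observed, null, p = basv_permutation(svs, bounds, g, n_perm=50, seed=0)
        # every placement contains a boundary, so no permutation can exceed
        # the (maximal) observed count and the strict ">" p is 0
        assert observed == 5
        assert (null == observed).all()
        assert p == 0.0

    def test_zero_boundaries_p_zero(self, toy_genome):
        svs = [make_consensus(pos1=100, pos2=5_000)]
        observed, null, p = basv_permutation(svs, [], toy_genome, n_perm=100, seed=1)
        assert observed == 0 and null.sum() == 0 and p == 0.0

    def test_size_preserved_and_in_bounds(self, toy_genome, toy_boundaries, rng):
        svs = [make_consensus(pos1=0, pos2=int(s)) for s in rng.integers(100, 900_000, size=30)]
        # permutation internals: rerun with identical seed and check the
        # null counts are reproducible (placement validity is asserted
        # inside via the weight construction erroring on impossible sizes)
        _, null1, _ = basv_permutation(svs, toy_boundaries, toy_genome, n_perm=200, seed=3)
        _, null2, _ = basv_permutation(svs, toy_boundaries, toy_genome, n_perm=200, seed=3)
        assert np.array_equal(null1, null2)

    def test_oversized_sv_rejected(self, toy_boundaries):
        g = GenomeRef(["chr1"], {"chr1": 1_000})
        sv = make_consensus(pos1=0, pos2=999_999)
        with pytest.raises(ValueError):
            basv_permutation([sv], toy_boundaries, g, n_perm=10, seed=0, max_size=2_000_000)

    def test_within_chrom_mode(self, toy_genome, toy_boundaries):
        svs = [make_consensus(pos1=1000, pos2=50_000, chrom1="chr2")]
        _, null, _ = basv_permutation(
            svs, toy_boundaries, toy_genome, n_perm=100, seed=4, within_chrom=True
        )
        assert len(null) == 100

    def test_null_calibration_uniform(self, toy_genome, toy_boundaries):
        rng = np.random.default_rng(17)
        chroms = toy_genome.chrom_names
        L = np.array([toy_genome.chrom_lengths[c] for c in chroms])
        ps = []
        for rep in range(300):
            sizes = np.minimum((2 ** rng.normal(14, 1.5, 200)).astype(int) + 100, 900_000)
            svs = []
            for s in sizes:
                w = np.maximum(L - s, 0)
                ci = rng.choice(len(chroms), p=w / w.sum())
                start = int(rng.integers(0, L[ci] - s + 1))
                svs.append(make_consensus(chrom1=chroms[ci], pos1=start, pos2=start + int(s)))
            obs, null, p = basv_permutation(svs, toy_boundaries, toy_genome, n_perm=500, seed=rep)
            # discrete statistic: uniformity holds after tie randomization
            gt = (null > obs).mean()
            eq = (null == obs).mean()
            assert p == gt
            ps.append(gt + rng.random() * eq)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestRecurrenceAndAdjacency:
    def _records(self, hits):
        """hits: list of (sample, boundary_id, event_class, role)."""
        from svmodes.tads import BASVRecord

        recs = []
        for sample, bid, cls, role in hits:
            genes = (GeneAnnotation("G", "chr1", 0, 10, role),) if role else ()
            recs.append(
                BASVRecord(sample, make_consensus(sample=sample), bid, ("active", "low"), genes, cls)
            )
        return recs

    def test_recurrence_threshold_inclusive(self):
        hits = [(f"s{i}", "b0", "DEL", None) for i in range(5)]
        recs = self._records(hits)
        table, frac, _ = recurrence_and_adjacency(recs, recurrence_threshold=5)
        assert table.iloc[0]["n_samples"] == 5
        assert frac == 1.0

    def test_fraction_over_all_ba_svs(self):
        hits = [(f"s{i}", "b0", "DEL", None) for i in range(5)]
        hits += [("s0", "b1", "DUP", None)]
        table, frac, _ = recurrence_and_adjacency(self._records(hits), recurrence_threshold=5)
        assert frac == pytest.approx(5 / 6)

    def test_fragile_site_distances(self):
        bounds = [
            TADBoundary("chr1", 1_000_000, 1_075_000, "b0"),
            TADBoundary("chr1", 5_000_000, 5_075_000, "b1"),
        ]
        sites = [FragileSite("FRA11H", "chr1", 1_725_000, 2_000_000)]
        recs = self._records([("s0", "b0", "DEL", None), ("s0", "b1", "DEL", None)])
        table, _, _ = recurrence_and_adjacency(recs, sites, bounds)
        by_id = table.set_index("boundary_id")
        assert by_id.loc["b0", "fragile_site_distance"] == 650_000
        assert by_id.loc["b1", "nearest_fragile_site"] == "FRA11H"

    def test_overlapping_fragile_site_distance_zero(self):
        bounds = [TADBoundary("chr1", 100, 200, "b0")]
        sites = [FragileSite("FRA1", "chr1", 150, 400)]
        recs = self._records([("s0", "b0", "DEL", None)])
        table, _, _ = recurrence_and_adjacency(recs, sites, bounds)
        assert table.iloc[0]["fragile_site_distance"] == 0

    def test_role_tables(self):
        hits = (
            [("s0", "b0", "DEL", "tumor-suppressor")] * 3
            + [("s1", "b1", "DUP", "tumor-suppressor")]
            + [("s2", "b2", "DEL", None)] * 2
            + [("s3", "b3", "complex", "oncogene")]
        )
        _, _, tables = recurrence_and_adjacency(self._records(hits))
        t = tables["deletion_vs_tumor_suppressor"]
        assert (t.a, t.b, t.c, t.d) == (3, 2, 1, 1)
        t2 = tables["complex_vs_oncogene"]
        assert (t2.a, t2.b, t2.c, t2.d) == (1, 0, 0, 6)


class TestBurdenCorrelation:
    def test_perfect_correlation(self):
        total = {f"s{i}": i for i in range(10)}
        df = basv_burden_correlation(total, total, {s: "g" for s in total})
        assert df.iloc[0]["r"] == pytest.approx(1.0)

    def test_independent_variables_near_zero(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            total = {f"s{i}": float(v) for i, v in enumerate(rng.normal(size=200))}
            ba = {f"s{i}": float(v) for i, v in enumerate(rng.normal(size=200))}
            df = basv_burden_correlation(total, ba, {s: "g" for s in total})
            if abs(df.iloc[0]["r"]) < 0.2:
                hits += 1
        assert hits >= 38

    def test_zero_variance_flagged(self):
        total = {f"s{i}": 5 for i in range(10)}
        ba = {f"s{i}": i for i in range(10)}
        df = basv_burden_correlation(total, ba, {s: "g" for s in total})
        assert df.iloc[0]["flagged"] and np.isnan(df.iloc[0]["r"])

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            basv_burden_correlation({"a": 1, "b": 2}, {"a": 1, "b": 2}, {"a": "g", "b": "g"})
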