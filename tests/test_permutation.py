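import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from loopmut import (
    GenomeLayout,
    Interval,
    IntervalSet,
    build_gwas_regions,
    circular_permutation_test,
    composition_test,
    laps_per_gene_test,
    recurrently_disrupted_loops,
    shift_curve,
)
from loopmut.permutation import _rotate

from conftest import coverage_mask, random_interval_df


def iset(triples, layout=None):
    return IntervalSet(
        pd.DataFrame(triples, columns=["chrom", "start", "end"]), layout=layout
    )


class TestRotation:
    def test_rotation_preserves_count_and_coverage(self):
        rng = np.random.default_rng(30)
        L = 100_000
        starts = np.sort(rng.choice(L - 500, size=50, replace=False))
        ends = starts + rng.integers(1, 500, size=50)
        total = int((ends - starts).sum())
        for off in [0, 1, 17_333, L - 1]:
            rs, re_, ri = _rotate(starts, ends, L, off)
            assert len(np.unique(ri)) == 50
            assert int((re_ - rs).sum()) == total
            assert (rs < re_).all() and (re_ <= L).all()

    def test_full_length_rotation_is_identity(self):
        starts = np.array([10, 50])
        ends = np.array([20, 70])
        rs, re_, _ = _rotate(starts, ends, 100, 100)
        np.testing.assert_array_equal(rs, starts)
        np.testing.assert_array_equal(re_, ends)

    def test_wrapped_interval_splits(self):
        rs, re_, ri = _rotate(np.array([90]), np.array([99]), 100, 5)
        # [90,99) + 5 -> [95,104) -> [95,100) and [0,4), one feature id
        assert rs.tolist() == [0, 95]
        assert re_.tolist() == [4, 100]
        assert ri.tolist() == [0, 0]


class TestCircularPermutation:
    def test_self_overlap_is_significant(self):
        rng = np.random.default_rng(31)
        layout = GenomeLayout([("chr1", 10_000_000)])
        starts = np.sort(rng.choice(9_990_000, size=100, replace=False))
        a = iset([("chr1", int(s), int(s) + 1000) for s in starts], layout)
        res = circular_permutation_test(a, a, layout, n_perm=999, seed=0)
        assert res.observed == 100
        assert res.p <= 0.002
        assert res.z > 3

    def test_empty_b_gives_p_one(self):
        layout = GenomeLayout([("chr1", 1_000_000)])
        a = iset([("chr1", 10, 1000)], layout)
        res = circular_permutation_test(a, IntervalSet(layout=layout), layout,
                                        n_perm=100, seed=0)
        assert res.observed == 0
        assert res.p == 1.0

    def test_empty_a_flagged_degenerate(self):
        layout = GenomeLayout([("chr1", 1_000_000)])
        b = iset([("chr1", 10, 1000)], layout)
        res = circular_permutation_test(IntervalSet(layout=layout), b, layout,
                                        n_perm=100, seed=0)
        assert res.degenerate
        assert res.p == 1.0

    def test_reproducible_under_seed(self):
        layout = GenomeLayout([("chr1", 1_000_000)])
        rng = np.random.default_rng(32)
        a = IntervalSet(random_interval_df(rng, "chr1", 40, 990_000), layout)
        b = IntervalSet(random_interval_df(rng, "chr1", 40, 990_000), layout)
        r1 = circular_permutation_test(a, b, layout, n_perm=200, seed=5)
        r2 = circular_permutation_test(a, b, layout, n_perm=200, seed=5)
        assert (r1.p, r1.null_mean, r1.z) == (r2.p, r2.null_mean, r2.z)

    def test_null_p_values_approximately_uniform(self):
        # independence: empirical p over repeated independent draws is ~U(0,1);
        # the sets are dense enough that the overlap count is near-continuous
        layout = GenomeLayout([("chr1", 10_000_000)])
        master = np.random.default_rng(33)
        ps = []
        for rep in range(200):
            a = IntervalSet(
                random_interval_df(master, "chr1", 600, 9_990_000, max_width=1000),
                layout,
            )
            b = IntervalSet(
                random_interval_df(master, "chr1", 600, 9_990_000, max_width=1000),
                layout,
            )
            res = circular_permutation_test(a, b, layout, n_perm=199, seed=master)
            ps.append(res.p)
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_null_z_calibrated(self):
        layout = GenomeLayout([("chr1", 2_000_000)])
        master = np.random.default_rng(34)
        zs = []
        for rep in range(100):
            a = IntervalSet(random_interval_df(master, "chr1", 40, 1_990_000), layout)
            b = IntervalSet(random_interval_df(master, "chr1", 40, 1_990_000), layout)
            res = circular_permutation_test(a, b, layout, n_perm=99, seed=master)
            zs.append(res.z)
        assert abs(np.mean(zs)) < 0.4
        assert 0.5 < np.std(zs) < 2.0


class TestShiftCurve:
    def test_offset_zero_reproduces_base_test(self):
        layout = GenomeLayout([("chr1", 1_000_000)])
        rng = np.random.default_rng(35)
        a = IntervalSet(random_interval_df(rng, "chr1", 30, 990_000), layout)
        b = IntervalSet(random_interval_df(rng, "chr1", 30, 990_000), layout)
        base = circular_permutation_test(a, b, layout, n_perm=99, seed=3)
        curve = shift_curve(a, b, layout, offsets=[0, 10_000], n_perm=99, seed=3)
        assert curve.z[0] == base.z

    def test_peak_at_zero_for_coincident_sets(self):
        layout = GenomeLayout([("chr1", 10_000_000)])
        rng = np.random.default_rng(36)
        starts = np.sort(rng.choice(9_990_000, size=80, replace=False))
        a = iset([("chr1", int(s), int(s) + 500) for s in starts], layout)
        curve = shift_curve(a, a, layout, offsets=[-5_000, 0, 5_000],
                            n_perm=199, seed=1)
        assert curve.z[1] == max(curve.z)
        assert curve.z[1] > curve.z[0] and curve.z[1] > curve.z[2]

    def test_full_chromosome_shift_is_wrap_identity(self):
        layout = GenomeLayout([("chr1", 1_000_000)])
        rng = np.random.default_rng(37)
        a = IntervalSet(random_interval_df(rng, "chr1", 30, 990_000), layout)
        b = IntervalSet(random_interval_df(rng, "chr1", 30, 990_000), layout)
        curve = shift_curve(a, b, layout, offsets=[0, 1_000_000], n_perm=99, seed=2)
        assert curve.observed[0] == curve.observed[1]
        assert curve.z[0] == curve.z[1]

    def test_missing_zero_offset_rejected(self):
        layout = GenomeLayout([("chr1", 1_000_000)])
        a = iset([("chr1", 0, 10)], layout)
        with pytest.raises(ValueError, match="0"):
            shift_curve(a, a, layout, offsets=[5_000], n_perm=10, seed=0)


class TestComposition:
    def _universe(self, n=100, layout=None):
        return iset([("chr1", 10_000 * i, 10_000 * i + 5_000) for i in range(n)],
                    layout)

    def test_product_of_marginals(self):
        # marginal fractions 0.16 and 0.69 compose to 0.11 at two decimals
        uni = self._universe(100)
        hs = iset([("chr1", 10_000 * i + 100, 10_000 * i + 200) for i in range(16)])
        dsb = iset([("chr1", 10_000 * i + 300, 10_000 * i + 400) for i in range(69)])
        results = composition_test(uni, {"HS": hs, "DSB": dsb})
        combo = [r for r in results if r.labels == ("HS", "DSB")][0]
        assert round(combo.expected_fraction, 2) == 0.11

    def test_full_marginal_is_neutral(self):
        uni = self._universe(50)
        full = iset([("chr1", 0, 500_000)])
        other = iset([("chr1", 10_000 * i + 100, 10_000 * i + 200) for i in range(20)])
        results = composition_test(uni, {"full": full, "other": other})
        combo = [r for r in results if r.labels == ("full", "other")][0]
        assert combo.expected_fraction == pytest.approx(20 / 50)

    def test_hypergeometric_matches_enumeration_oracle(self):
        # N=20, K=10, n=10, x=10: enumerate all C(20,10) draws
        uni = self._universe(20)
        in_a = iset([("chr1", 10_000 * i + 1, 10_000 * i + 2) for i in range(10)])
        in_b = iset([("chr1", 10_000 * i + 3, 10_000 * i + 4) for i in range(10)])
        results = composition_test(uni, {"A": in_a, "B": in_b},
                                   combos=[("A", "B")])
        combo = [r for r in results if len(r.labels) == 2][0]
        # oracle: P(X >= x) by full enumeration over hypergeometric support
        N, K, n, x = 20, 10, 10, combo.observed_count
        total = math.comb(N, n)
        p_exact = sum(
            math.comb(K, k) * math.comb(N - K, n - k)
            for k in range(max(x, n + K - N), min(K, n) + 1)
        ) / total
        assert combo.p == pytest.approx(p_exact, rel=1e-12)

    def test_unknown_label_rejected(self):
        uni = self._universe(10)
        with pytest.raises(KeyError, match="nope"):
            composition_test(uni, {"A": uni}, combos=[("A", "nope")])

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            composition_test(IntervalSet(), {})


class TestGwasRegions:
    def test_symmetric_extension(self):
        snps = iset([("chr1", 10_000, 10_001)])
        out = build_gwas_regions(snps, flank=5_000)
        iv = next(iter(out))
        assert (iv.start, iv.end) == (5_000, 15_001)

    def test_nearby_snps_merge(self):
        snps = iset([("chr1", 10_000, 10_001), ("chr1", 18_000, 18_001)])
        out = build_gwas_regions(snps, flank=5_000)
        assert len(out) == 1

    def test_clipping_at_chromosome_bounds(self):
        layout = GenomeLayout([("chr1", 20_000)])
        snps = iset([("chr1", 1_000, 1_001), ("chr1", 19_000, 19_001)], layout)
        out = build_gwas_regions(snps, flank=5_000, layout=layout)
        ivs = list(out)
        assert ivs[0].start == 0
        assert ivs[-1].end == 20_000

    def test_merged_span_matches_mask_oracle(self):
        rng = np.random.default_rng(38)
        L = 1_000_000
        pos = rng.choice(L - 20_000, size=200, replace=False) + 10_000
        snps = iset([("chr1", int(p), int(p) + 1) for p in pos])
        out = build_gwas_regions(snps, flank=5_000)
        mask = np.zeros(L + 10_001, dtype=bool)
        for p in pos:
            mask[p - 5_000 : p + 5_001] = True
        assert out.total_bp == int(mask.sum())


class TestDisruptedLoops:
    def _loops(self):
        return pd.DataFrame(
            [("L1", "chr1", 0, 5_000, "chr1", 100_000, 105_000),
             ("L2", "chr1", 200_000, 205_000, "chr1", 300_000, 305_000)],
            columns=["loop_id", "chrom1", "start1", "end1",
                     "chrom2", "start2", "end2"],
        )

    def test_threshold_retention(self):
        bp = pd.DataFrame(
            [("S1", "chr1", 1_000 + i) for i in range(5)],
            columns=["sample_id", "chrom", "pos"],
        )
        out = recurrently_disrupted_loops(self._loops(), bp, min_hits=5)
        assert out["loop_id"].tolist() == ["L1"]
        assert out["n_hits"].item() == 5

    def test_no_hits_empty(self):
        bp = pd.DataFrame([("S1", "chr1", 50_000)],
                          columns=["sample_id", "chrom", "pos"])
        assert len(recurrently_disrupted_loops(self._loops(), bp, min_hits=1)) == 0

    def test_distinct_sample_mode(self):
        bp = pd.DataFrame(
            [("S1", "chr1", 1_000), ("S1", "chr1", 2_000), ("S2", "chr1", 101_000)],
            columns=["sample_id", "chrom", "pos"],
        )
        by_bp = recurrently_disrupted_loops(self._loops(), bp, min_hits=2)
        by_sample = recurrently_disrupted_loops(self._loops(), bp, min_hits=2,
                                                distinct_samples=True)
        assert by_bp["n_hits"].item() == 3
        assert by_sample["n_hits"].item() == 2

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            recurrently_disrupted_loops(self._loops(), pd.DataFrame(
                columns=["sample_id", "chrom", "pos"]), min_hits=0)

    def test_tallies_match_brute_force(self):
        rng = np.random.default_rng(39)
        loops = self._loops()
        bp = pd.DataFrame({
            "sample_id": rng.choice(["S1", "S2", "S3"], 500),
            "chrom": "chr1",
            "pos": rng.integers(0, 400_000, 500),
        })
        out = recurrently_disrupted_loops(loops, bp, min_hits=1)
        for row in loops.itertuples(index=False):
            expected = (
                ((bp["pos"] >= row.start1) & (bp["pos"] < row.end1)).sum()
                + ((bp["pos"] >= row.start2) & (bp["pos"] < row.end2)).sum()
            )
            got = out.loc[out["loop_id"] == row.loop_id, "n_hits"]
            assert (got.item() if len(got) else 0) == expected


class TestLapsPerGene:
    def test_identical_gene_sets_equal_rates(self):
        genes = iset([("chr1", 10_000 * i, 10_000 * i + 2_000) for i in range(20)])
        laps = iset([("chr1", 10_000 * i + 500, 10_000 * i + 1_000) for i in range(7)])
        ra, rb, p = laps_per_gene_test(genes, genes, laps)
        assert ra == rb
        assert p == pytest.approx(1.0)

    def test_one_sided_tiling(self):
        genes_a = iset([("chr1", 10_000 * i, 10_000 * i + 2_000) for i in range(20)])
        genes_b = iset([("chr2", 10_000 * i, 10_000 * i + 2_000) for i in range(20)])
        laps = iset([("chr1", 10_000 * i, 10_000 * i + 5_000) for i in range(20)])
        ra, rb, p = laps_per_gene_test(genes_a, genes_b, laps)
        assert ra == 1.0
        assert rb == 0.0
        assert p < 1e-6

    def test_p_matches_chi_square_oracle(self):
        genes_a = iset([("chr1", 10_000 * i, 10_000 * i + 2_000) for i in range(100)])
        genes_b = iset([("chr1", 10_000 * i + 3_000, 10_000 * i + 4_000)
                        for i in range(100)])
        laps = iset([("chr1", 10_000 * i + 500, 10_000 * i + 1_000)
                     for i in range(77)]
                    + [("chr1", 10_000 * i + 3_200, 10_000 * i + 3_300)
                       for i in range(47)])
        ra, rb, p = laps_per_gene_test(genes_a, genes_b, laps)
        assert (ra, rb) == (0.77, 0.47)
        # closed-form 2x2 chi-square without continuity correction
        x_a, x_b, n = 77, 47, 100
        p_pool = (x_a + x_b) / (2 * n)
        chi2 = (x_a - n * p_pool) ** 2 * (
            1 / (n * p_pool) + 1 / (n * (1 - p_pool))
        ) * 2 / 2
        expected = [n * p_pool, n * (1 - p_pool), n * p_pool, n * (1 - p_pool)]
        observed = [x_a, n - x_a, x_b, n - x_b]
        chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
        assert p == pytest.approx(stats.chi2.sf(chi2, 1), rel=1e-9)

    def test_empty_gene_set_rejected(self):
        genes = iset([("chr1", 0, 1_000)])
        with pytest.raises(ValueError):
            laps_per_gene_test(genes, IntervalSet(), genes)
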