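"""Size factors, scaled fold changes, depth/bagplot, quartiles and GSEA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from identiscape.exprstats import (
    bagplot,
    gene_set_score,
    gsea_es,
    quartile_enrichment,
    rank_by_class_difference,
    scale_and_fc,
    size_factors,
    tukey_depth,
)
from identiscape.identity import IdentityCall


class TestSizeFactors:
    def test_direct_formula_two_genes(self):
        counts = pd.DataFrame({"s1": [2, 10], "s2": [4, 20]})
        assert np.allclose(size_factors(counts), [1 / np.sqrt(2), np.sqrt(2)])

    def test_identical_columns_equal_factors(self):
        counts = pd.DataFrame({"a": [3, 7, 1], "b": [3, 7, 1], "c": [3, 7, 1]})
        assert np.allclose(size_factors(counts), 1.0)

    def test_doubling_a_column_doubles_its_relative_factor(self, rng):
        # factors are defined up to a common scale (the geometric-mean
        # reference moves too), so the invariant lives on factor ratios
        counts = pd.DataFrame(rng.poisson(20, size=(50, 3)) + 1, columns=list("abc"))
        base = size_factors(counts)
        doubled = counts.copy()
        doubled["b"] = 2 * doubled["b"]
        got = size_factors(doubled)
        assert (got["b"] / got["a"]) / (base["b"] / base["a"]) == pytest.approx(2.0)

    def test_no_all_positive_gene_errors(self):
        with pytest.raises(ValueError):
            size_factors(pd.DataFrame({"a": [0, 5], "b": [5, 0]}))


class TestScaleAndFc:
    def _design(self, n_base=2, n_pert=2):
        cols = [f"c{i}" for i in range(n_base)] + [f"t{i}" for i in range(n_pert)]
        design = {c: ("ctrl" if c.startswith("c") else "pert") for c in cols}
        return cols, design

    def test_retained_values_have_zero_mean_unit_sd(self, rng):
        cols, design = self._design()
        expr = pd.DataFrame(
            rng.normal(7, 2, size=(1000, 4)),
            index=[f"g{i:04d}" for i in range(1000)],
            columns=cols,
        )
        fc = scale_and_fc(expr, design, "ctrl")
        assert fc.attrs["n_dropped"] == 200
        assert len(fc) == 800
        kept = expr.loc[fc.index]
        scaled = (kept - fc.attrs["global_mean"]) / fc.attrs["global_sd"]
        assert scaled.to_numpy().mean() == pytest.approx(0.0, abs=1e-12)
        assert scaled.to_numpy().std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_ten_genes_drop_fifth_leaves_eight(self, rng):
        cols, design = self._design()
        expr = pd.DataFrame(rng.normal(size=(10, 4)), columns=cols,
                            index=[f"g{i}" for i in range(10)])
        assert len(scale_and_fc(expr, design, "ctrl")) == 8

    def test_constant_shift_gives_fc_delta_over_sd(self, rng):
        cols, design = self._design()
        base = rng.normal(5, 1, size=(200, 2))
        delta = 1.7
        expr = pd.DataFrame(
            np.column_stack([base, base + delta]), columns=cols,
            index=[f"g{i:03d}" for i in range(200)],
        )
        fc = scale_and_fc(expr, design, "ctrl")
        assert np.allclose(fc["scaled_fc"], delta / fc.attrs["global_sd"], atol=1e-12)

    def test_scaled_fc_is_monotone_transform_of_raw_fc(self, rng):
        cols, design = self._design(3, 3)
        expr = pd.DataFrame(rng.normal(6, 2, size=(300, 6)), columns=cols,
                            index=[f"g{i:03d}" for i in range(300)])
        fc = scale_and_fc(expr, design, "ctrl")
        rho = sps.spearmanr(fc["scaled_fc"], fc["raw_fc"]).statistic
        assert rho == pytest.approx(1.0)

    def test_zero_global_sd_errors(self):
        cols, design = self._design()
        expr = pd.DataFrame(np.full((10, 4), 3.0), columns=cols,
                            index=[f"g{i}" for i in range(10)])
        with pytest.raises(ValueError, match="standard deviation"):
            scale_and_fc(expr, design, "ctrl")


class TestTukeyDepth:
    @staticmethod
    def depth_oracle(pts):
        """Exhaustive direction scan over all point-pair normals."""
        n = len(pts)
        out = np.empty(n, dtype=int)
        for i in range(n):
            diff = pts - pts[i]
            best = n
            for j in range(n):
                if j == i:
                    continue
                v = pts[j] - pts[i]
                for u in (np.array([-v[1], v[0]]), np.array([v[1], -v[0]])):
                    for eps in (0.0, 1e-9, -1e-9):
                        c, s = np.cos(eps), np.sin(eps)
                        ru = np.array([c * u[0] - s * u[1], s * u[0] + c * u[1]])
                        best = min(best, int(np.sum(diff @ ru >= -1e-12)))
            out[i] = best
        return out

    @pytest.mark.parametrize("n", [10, 60, 150])
    def test_matches_exhaustive_direction_scan(self, n, rng):
        pts = rng.normal(size=(n, 2))
        assert np.array_equal(tukey_depth(pts), self.depth_oracle(pts))

    def test_center_of_symmetric_cross_is_deepest(self):
        pts = np.array([[0, 0], [0, 1], [1, 0], [0, -1], [-1, 0]], dtype=float)
        depths = tukey_depth(pts)
        assert depths[0] == 3 and (depths[1:] == 1).all()


class TestBagplot:
    def test_bag_holds_exactly_half_the_points(self, rng):
        for seed in (0, 1, 2):
            pts = np.random.default_rng(seed).normal(size=(100, 2))
            bp = bagplot(pts)
            assert int(bp.in_bag.sum()) == 50

    def test_odd_count_uses_ceiling(self, rng):
        pts = rng.normal(size=(41, 2))
        assert int(bagplot(pts).in_bag.sum()) == 21

    def test_diamond_center_is_depth_median(self):
        pts = np.array([[0, 0], [0, 2], [2, 0], [0, -2], [-2, 0]], dtype=float)
        bp = bagplot(pts)
        assert np.allclose(bp.depth_median, [0, 0])

    def test_loop_contains_bag(self, rng):
        pts = rng.normal(size=(80, 2)) * [3.0, 1.0]
        bp = bagplot(pts)
        c = bp.depth_median
        # loop vertices are the bag vertices inflated 3x about the median
        assert np.allclose(bp.loop - c, 3.0 * (bp.bag - c))
        assert not bp.outliers or max(bp.outliers) < 80

    def test_outliers_lie_outside_loop_others_inside(self, rng):
        pts = rng.normal(size=(60, 2))
        pts[0] = [40.0, 40.0]  # gross outlier
        bp = bagplot(pts)
        assert 0 in bp.outliers

    def test_interior_recomputation_preserves_bag_membership_count(self, rng):
        pts = rng.normal(size=(90, 2))
        bp = bagplot(pts)
        interior = pts[[i for i in range(90) if i not in bp.outliers]]
        bp2 = bagplot(interior)
        assert int(bp2.in_bag.sum()) == int(np.ceil(len(interior) / 2))

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError, match="univariate"):
            bagplot(pts)


class TestQuartileEnrichment:
    def _fc(self, scaled):
        return pd.DataFrame(
            {"scaled_fc": scaled, "raw_fc": scaled, "baseline": 5.0},
            index=[f"g{i:03d}" for i in range(len(scaled))],
        )

    def _calls(self, id_genes, n):
        return [
            IdentityCall(f"g{i:03d}", "ID" if f"g{i:03d}" in id_genes else "OTHER")
            for i in range(n)
        ]

    def test_relative_fractions_are_ratios_to_q1(self):
        # 40 repressed genes; ID fractions per quartile 0.1/0.1/0.2/0.4
        scaled = -np.linspace(0.01, 1.0, 40)  # g000 least repressed ... g039 most
        id_genes = {"g000", "g010", "g020", "g021", "g030", "g031", "g032", "g033"}
        res = quartile_enrichment(self._fc(scaled), self._calls(id_genes, 40))
        assert not res.relative_is_absolute
        assert np.allclose(res.table["relative"], [1, 1, 2, 4])

    def test_remainder_genes_go_to_earlier_quartiles(self):
        res = quartile_enrichment(
            self._fc(-np.linspace(0.1, 1, 7)), self._calls(set(), 7)
        )
        assert list(res.table["n"]) == [2, 2, 2, 1]

    def test_q4_holds_most_repressed_genes(self):
        scaled = -np.linspace(0.01, 1.0, 8)
        id_genes = {"g006", "g007"}  # the two most repressed
        res = quartile_enrichment(self._fc(scaled), self._calls(id_genes, 8))
        assert res.table.loc[3, "n_class"] == 2
        assert res.table.loc[0, "n_class"] == 0

    def test_zero_q1_fraction_returns_absolute_with_flag(self):
        scaled = -np.linspace(0.01, 1.0, 8)
        res = quartile_enrichment(self._fc(scaled), self._calls({"g007"}, 8))
        assert res.relative_is_absolute
        assert res.table["relative"].iloc[0] == 0.0

    def test_uniform_placement_relative_near_one(self, rng):
        n = 4000
        scaled = -rng.uniform(0.01, 1.0, n)
        ids = {f"g{i:03d}" for i in rng.choice(n, 1000, replace=False)}
        fc = pd.DataFrame(
            {"scaled_fc": scaled}, index=[f"g{i:03d}" for i in range(n)]
        )
        calls = [
            IdentityCall(g, "ID" if g in ids else "OTHER") for g in fc.index
        ]
        res = quartile_enrichment(fc, calls)
        assert np.allclose(res.table["relative"], 1.0, atol=0.25)
        assert res.chi2_pvalue > 0.01


class TestGsea:
    def _ranked(self, n=10):
        return pd.Series(np.linspace(5, -5, n), index=[f"g{i}" for i in range(n)])

    def test_weight_zero_top_prefix_gives_unit_es(self):
        res = gsea_es(self._ranked(), {"g0", "g1"}, weight=0.0, n_perm=50, seed=1)
        assert res.es == pytest.approx(1.0)

    def test_weight_zero_equals_ks_running_statistic(self, rng):
        ranked = self._ranked(30)
        gs = set(rng.choice(ranked.index, 8, replace=False))
        res = gsea_es(ranked, gs, weight=0.0, n_perm=10, seed=0)
        # direct KS prefix recomputation
        hit = np.array([g in gs for g in ranked.index])
        m, N = hit.sum(), len(ranked)
        run = np.cumsum(np.where(hit, 1 / m, -1 / (N - m)))
        assert np.allclose(res.running_sum, run, atol=1e-12)
        assert res.es == pytest.approx(run[np.argmax(np.abs(run))])

    def test_weighted_es_matches_direct_recomputation(self, rng):
        ranked = self._ranked(25)
        gs = set(rng.choice(ranked.index, 6, replace=False))
        res = gsea_es(ranked, gs, weight=1.0, n_perm=10, seed=0)
        hit = np.array([g in gs for g in ranked.index])
        w = np.abs(ranked.to_numpy())
        run = np.cumsum(np.where(hit, w / w[hit].sum(), -1 / (len(ranked) - hit.sum())))
        assert np.allclose(res.running_sum, run, atol=1e-12)

    def test_full_or_disjoint_gene_set_errors(self):
        ranked = self._ranked()
        with pytest.raises(ValueError):
            gsea_es(ranked, set(ranked.index), n_perm=5)
        with pytest.raises(ValueError):
            gsea_es(ranked, {"absent"}, n_perm=5)

    def test_permutations_reproducible_under_seed(self):
        ranked = self._ranked(20)
        a = gsea_es(ranked, {"g1", "g3", "g5"}, n_perm=100, seed=7)
        b = gsea_es(ranked, {"g1", "g3", "g5"}, n_perm=100, seed=7)
        assert a.nes == b.nes and a.fdr == b.fdr

    def test_rank_metric_is_mean_class_difference(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(10, 4)),
            columns=["a1", "a2", "b1", "b2"],
            index=[f"g{i}" for i in range(10)],
        )
        design = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        metric = rank_by_class_difference(expr, design, "A", "B")
        want = expr[["a1", "a2"]].mean(1) - expr[["b1", "b2"]].mean(1)
        assert np.allclose(metric.sort_index(), want.sort_index())
        assert (np.diff(metric.to_numpy()) <= 0).all()


class TestGeneSetScore:
    def test_singleton_set_returns_gene_row(self):
        m = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["a", "b"], columns=["c1", "c2"])
        assert np.allclose(gene_set_score(m, ["b"]), [3.0, 4.0])

    def test_hand_computed_mean_on_toy(self):
        m = pd.DataFrame(
            [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]], index=["a", "b", "c"],
            columns=["c1", "c2"],
        )
        assert np.allclose(gene_set_score(m, ["a", "c"]), [3.0, 4.0])

    def test_constant_matrix_gives_constant_score(self):
        m = pd.DataFrame(np.full((4, 3), 2.5), index=list("abcd"))
        assert np.allclose(gene_set_score(m, ["a", "b"]), 2.5)

    def test_empty_or_missing_gene_errors(self):
        m = pd.DataFrame([[1.0]], index=["a"])
        with pytest.raises(ValueError):
            gene_set_score(m, [])
        with pytest.raises(ValueError):
            gene_set_score(m, ["zz"])
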