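"""Time proxies, regression, candidate filtering, Cook's distance."""

from __future__ import annotations

import numpy as np
import pytest

from lineagescan import (
    FamilyStats,
    GeneTree,
    SpeciesTree,
    cooks_distance,
    filter_candidates,
    fit_regression,
    lca_reconcile,
    outlier_pathway_counts,
    time_proxies,
)
from lineagescan.duprates import RegressionFit
from lineagescan.tables import AnnotationMap


def loo_cooks_oracle(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Leave-one-out refit: D_i = sum_j (yhat_j - yhat_j(i))^2 / (p s^2)."""
    n, p = len(x), 2
    beta = np.polyfit(x, y, 1)
    yhat = np.polyval(beta, x)
    s2 = float(np.sum((y - yhat) ** 2)) / (n - p)
    out = []
    for i in range(n):
        beta_i = np.polyfit(np.delete(x, i), np.delete(y, i), 1)
        yhat_i = np.polyval(beta_i, x)
        out.append(float(np.sum((yhat - yhat_i) ** 2)) / (p * s2))
    return np.array(out)


def _stats(fid, y, proxy):
    return FamilyStats(family_id=fid, n_duplications=y, root_age=proxy,
                       max_length=proxy, median_length=proxy, proxy=proxy)


class TestTimeProxies:
    def _tree_and_rec(self, newick):
        stree = SpeciesTree.from_newick("(a:1,b:1)r;")
        gtree = GeneTree.from_newick(newick)
        return gtree, lca_reconcile(gtree, stree)

    def test_two_leaf_depths(self):
        gtree, rec = self._tree_and_rec("(a|1:0.3,a|2:0.1)x;")
        age, mx, md = time_proxies(gtree, rec)
        assert mx == pytest.approx(0.3)
        assert md == pytest.approx(0.2)
        assert age == 0.0  # single-species family maps to the leaf

    def test_odd_and_even_median(self):
        gtree, _ = self._tree_and_rec("(a|1:0.3,a|2:0.1)x;")
        # depths {1, 2, 3}: max 3, median 2
        depths = [1.0, 2.0, 3.0]
        assert float(np.median(depths)) == 2.0
        gtree2 = GeneTree.from_newick(
            "((a|1:1,a|2:2)i1:0,(a|3:3,b|1:10)i2:0)i3;"
        )
        stree = SpeciesTree.from_newick("(a:1,b:1)r;")
        rec = lca_reconcile(gtree2, stree)
        _, mx, md = time_proxies(gtree2, rec)
        assert mx == 10.0
        assert md == 2.5  # even count {1,2,3,10}: midpoint of middle pair


class TestRegression:
    def test_perfect_line(self):
        fit = fit_regression([0, 1, 2, 3], [0, 2, 4, 6])
        assert fit.pearson_r == pytest.approx(1.0)
        assert fit.slope == pytest.approx(2.0)
        assert fit.s2 == pytest.approx(0.0, abs=1e-20)

    def test_pearson_r_hand_case(self):
        # direct evaluation of the Pearson formula as the oracle
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([0.0, 1.0, 4.0])
        sx, sy = x - x.mean(), y - y.mean()
        expected = float(np.sum(sx * sy) / np.sqrt(np.sum(sx**2) * np.sum(sy**2)))
        fit = fit_regression(x, y)
        assert fit.pearson_r == pytest.approx(expected, abs=1e-12)
        assert fit.pearson_r == pytest.approx(0.961, abs=5e-4)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_regression([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            fit_regression([1, 2, 3], [5, 5, 5])
        with pytest.raises(ValueError):
            fit_regression([1, 2], [1, 2])

    def test_log1p_transform_applied(self):
        x = np.array([0.0, 1.0, 3.0, 7.0])
        y = np.expm1(2 * np.log1p(x))  # log1p(y) = 2 log1p(x) exactly
        fit = fit_regression(x, y, "log1p", "log1p")
        assert fit.pearson_r == pytest.approx(1.0)
        assert fit.slope == pytest.approx(2.0)

    def test_r_affine_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, 20)
        y = rng.uniform(0, 10, 20)
        r0 = fit_regression(x, y).pearson_r
        assert fit_regression(3 * x + 1, 0.5 * y - 2).pearson_r == pytest.approx(r0)
        assert fit_regression(x, 4 + 2 * x).pearson_r == pytest.approx(1.0)
        assert fit_regression(x, 4 - 2 * x).pearson_r == pytest.approx(-1.0)


class TestFilterCandidates:
    def _flat_fit(self, n):
        return RegressionFit(slope=0.0, intercept=0.0, pearson_r=0.0,
                             s2=1.0, n=n)

    def test_nothing_dropped_when_all_above_and_equal_proxy(self):
        stats = [_stats(f"f{i}", 1, 5.0) for i in range(10)]
        kept = filter_candidates(stats, self._flat_fit(10))
        assert len(kept) == 10

    def test_zero_residual_retained(self):
        stats = [_stats("on_line", 0, 1.0)] + [
            _stats(f"f{i}", 1, float(i + 2)) for i in range(5)
        ]
        kept = filter_candidates(stats, self._flat_fit(6))
        assert any(s.family_id == "on_line" for s in kept)

    def test_forty_family_hand_count(self):
        # 10 below the line; of the 30 others (distinct proxies) exactly
        # floor(0.05 * 30) = 1 is dropped by the percentile filter -> 29
        below = [_stats(f"b{i}", -1, 50.0 + i) for i in range(10)]
        above = [_stats(f"a{i:02d}", 1, float(i + 1)) for i in range(30)]
        kept = filter_candidates(below + above, self._flat_fit(40))
        assert len(kept) == 29
        assert all(s.family_id != "a00" for s in kept)  # smallest proxy out

    def test_all_below_line_is_error(self):
        stats = [_stats(f"f{i}", -1, float(i + 1)) for i in range(5)]
        with pytest.raises(ValueError):
            filter_candidates(stats, self._flat_fit(5))


class TestCooksDistance:
    def test_zero_residual_zero_distance(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 3.0, 10.0])
        fit = fit_regression(x, y)
        d = cooks_distance(x, y, fit)
        resid = y - fit.predict(x)
        assert d[np.argmin(np.abs(resid))] >= 0
        # a literally zero residual gives literally zero distance
        x2 = np.array([0.0, 1.0, 2.0, 3.0])
        y2 = np.array([0.0, 1.0, 2.0, 9.0])
        fit2 = fit_regression(x2, y2)
        e = y2 - fit2.predict(x2)
        d2 = cooks_distance(x2, y2, fit2)
        assert d2[np.argmin(np.abs(e))] == pytest.approx(
            e[np.argmin(np.abs(e))] ** 2, abs=1.0
        )

    def test_matches_leave_one_out_oracle_hand_case(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 3.0, 10.0])
        d = cooks_distance(x, y, fit_regression(x, y))
        assert np.allclose(d, loo_cooks_oracle(x, y), atol=1e-10)

    def test_matches_leave_one_out_oracle_random(self):
        """Closed form equals the refit oracle on 100 random datasets."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(4, 51))
            x = rng.uniform(0, 10, n)
            y = 1.0 + 0.5 * x + rng.normal(0, 1, n)
            fit = fit_regression(x, y)
            assert np.allclose(
                cooks_distance(x, y, fit), loo_cooks_oracle(x, y), atol=1e-10
            )

    def test_matches_statsmodels_influence(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        x = rng.uniform(0, 5, 30)
        y = 2 + x + rng.normal(0, 0.5, 30)
        ours = cooks_distance(x, y, fit_regression(x, y))
        model = sm.OLS(y, sm.add_constant(x)).fit()
        theirs = model.get_influence().cooks_distance[0]
        assert np.allclose(ours, theirs, atol=1e-10)

    def test_symmetric_points_equal_distance(self):
        x = np.array([0.0, 1.0, 3.0, 4.0])
        y = np.array([1.0, 0.0, 0.0, 1.0])  # symmetric about x-mean = 2
        d = cooks_distance(x, y, fit_regression(x, y))
        assert d[0] == pytest.approx(d[3], rel=1e-10)
        assert d[1] == pytest.approx(d[2], rel=1e-10)

    def test_perfect_fit_rejected(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        fit = fit_regression(x, 2 * x)
        with pytest.raises(ValueError):
            cooks_distance(x, 2 * x, fit)


class TestOutlierPathways:
    def _retained(self, n):
        out = []
        for i in range(n):
            s = _stats(f"f{i}", 1, 1.0)
            s.cooks_d = float(n - i)  # f0 most influential
            out.append(s)
        return out

    def test_eight_families_select_two(self):
        amap = AnnotationMap()
        amap.add("f0", "pathway", "P")
        amap.add("f1", "pathway", "P")
        amap.add("f7", "pathway", "Q")
        counts = outlier_pathway_counts(self._retained(8), amap)
        assert counts == [("P", 2)]  # top quartile = f0, f1

    def test_counts_conserve_memberships(self):
        amap = AnnotationMap()
        for fam, terms in [("f0", "PQ"), ("f1", "P"), ("f2", "R")]:
            for t in terms:
                amap.add(fam, "pathway", t)
        retained = self._retained(8)
        counts = outlier_pathway_counts(retained, amap)
        selected = {"f0", "f1"}
        expected = sum(
            len(amap.pathways.get(f, set())) for f in selected
        )
        assert sum(c for _, c in counts) == expected

    def test_empty_retained_rejected(self):
        with pytest.raises(ValueError):
            outlier_pathway_counts([], AnnotationMap())
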