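import numpy as np
import pandas as pd
import pytest

from conftest import make_catalog
from isousage.qc_pseudobulk import PseudobulkMatrix
from isousage.usage_dm import (
    GAMMA_BOUNDS,
    ContrastError,
    NotTestable,
    dm_loglik,
    estimate_precision,
    feature_level_test,
    fit_dm_gene,
    fit_proportions,
    run_usage_scan,
)


def sim_dm_gene(rng, J, units, depth, gamma, pi_by_unit):
    x = np.zeros((units, J), int)
    for u in range(units):
        p = rng.dirichlet(gamma * np.asarray(pi_by_unit[u]))
        x[u] = rng.multinomial(depth, p)
    return x


class TestPrecision:
    def test_proportional_splits_hit_upper_bound(self):
        x = np.tile([50, 50], (6, 1))
        assert estimate_precision(x) == pytest.approx(GAMMA_BOUNDS[1], rel=1e-6)

    def test_maximal_overdispersion_gives_small_gamma(self):
        x = np.array([[100, 0], [0, 100]])
        gamma = estimate_precision(x)
        assert gamma < 5
        # grid verification: the profile likelihood really is maximized low
        grid = np.linspace(np.log(1e-2), np.log(1e6), 60)
        lls = [fit_proportions(x, float(np.exp(g)))[1] for g in grid]
        assert np.exp(grid[int(np.argmax(lls))]) < 5

    def test_parameter_recovery_from_dm_simulation(self):
        rng = np.random.default_rng(2)
        pi = np.array([0.5, 0.3, 0.2])
        x = sim_dm_gene(rng, 3, 20, 500, 30.0, [pi] * 20)
        assert 15 <= estimate_precision(x) <= 60

    def test_all_zero_gene_not_testable(self):
        with pytest.raises(NotTestable):
            estimate_precision(np.zeros((4, 2)))


class TestGeneFit:
    def test_identical_groups_give_null_result(self):
        x = np.tile([400, 200, 100], (10, 1))
        fit = fit_dm_gene(x, np.array(["a"] * 5 + ["b"] * 5))
        assert fit.lr_stat == pytest.approx(0.0, abs=1e-4)
        assert fit.p_value > 0.99
        assert fit.df == 2

    def test_strong_switch_detected_and_mle_matches_grid(self):
        x = np.vstack([np.tile([90, 10], (5, 1)), np.tile([10, 90], (5, 1))])
        labels = np.array(["a"] * 5 + ["b"] * 5)
        fit = fit_dm_gene(x, labels)
        assert fit.p_value < 1e-6
        # dense-grid check of the fitted log-likelihood maxima at the gammas used
        grid = np.linspace(1e-4, 1 - 1e-4, 4001)
        def grid_max(sub, gamma):
            return max(dm_loglik(sub, gamma * np.array([p, 1 - p]))
                       for p in grid)
        assert fit.loglik_null >= grid_max(x, fit.gamma_null) - 1e-3
        assert fit.loglik_full >= (grid_max(x[:5], fit.gamma)
                                   + grid_max(x[5:], fit.gamma)) - 1e-3

    def test_zero_total_units_excluded(self):
        x = np.array([[50, 50], [0, 0], [30, 70], [60, 40]])
        fit = fit_dm_gene(x, np.array(["a", "a", "b", "b"]))
        assert fit.df == 1  # 2 groups still present after dropping the zero unit

    def test_group_entirely_zero_not_testable(self):
        x = np.array([[50, 50], [0, 0]])
        with pytest.raises(NotTestable):
            fit_dm_gene(x, np.array(["a", "b"]))

    def test_single_isoform_not_testable(self):
        with pytest.raises(NotTestable):
            fit_dm_gene(np.array([[5], [7]]), np.array(["a", "b"]))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 200, size=(8, 3))
        labels = np.array(["a", "b"] * 4)
        fit = fit_dm_gene(x, labels)
        perm = rng.permutation(8)
        fit2 = fit_dm_gene(x[perm], labels[perm])
        assert fit.lr_stat == pytest.approx(fit2.lr_stat, rel=1e-9)
        assert fit.p_value == pytest.approx(fit2.p_value, rel=1e-9)

    def test_multinomial_limit_matches_g_test(self):
        """At the gamma upper bound the DM LRT approaches the classical
        multinomial G-test on pooled per-group counts."""
        x = np.array([[40, 25, 10], [35, 30, 12], [12, 40, 22], [9, 45, 30]])
        labels = np.array(["a", "a", "b", "b"])
        fit = fit_dm_gene(x, labels, gamma=GAMMA_BOUNDS[1])
        # G statistic on pooled counts
        g_stat = 0.0
        pooled = x.sum(axis=0)
        for grp in ("a", "b"):
            o = x[labels == grp].sum(axis=0)
            e = pooled * o.sum() / pooled.sum()
            g_stat += 2 * np.sum(o * np.log(o / e))
        assert fit.lr_stat == pytest.approx(g_stat, rel=0.02)

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(9)
        labels = np.array(["a"] * 6 + ["b"] * 6)
        ps = []
        for _ in range(200):
            pi = rng.dirichlet([2.0, 2.0, 2.0])
            x = sim_dm_gene(rng, 3, 12, 500, 30.0, [pi] * 12)
            ps.append(fit_dm_gene(x, labels).p_value)
        frac = np.mean(np.array(ps) < 0.05)
        assert 0.005 <= frac <= 0.12  # loose band at n=200


class TestFeatureLevel:
    def test_symmetric_switch_equal_p_opposite_effects(self):
        x = np.vstack([np.tile([80, 20], (4, 1)), np.tile([20, 80], (4, 1))])
        labels = np.array(["a"] * 4 + ["b"] * 4)
        fit = fit_dm_gene(x, labels)
        ft = feature_level_test(fit, x, labels, group_of_interest="a")
        assert ft["p_value"][0] == pytest.approx(ft["p_value"][1], rel=1e-9)
        assert ft["effect"][0] == pytest.approx(-ft["effect"][1], rel=1e-9)
        assert ft["direction"].tolist() == ["high usage", "low usage"]

    def test_stable_isoform_in_switching_gene_is_null(self):
        rng = np.random.default_rng(4)
        # isoform 3 fixed at 40% usage in both groups; 1 and 2 switch
        pi_a, pi_b = [0.45, 0.15, 0.4], [0.15, 0.45, 0.4]
        x = np.vstack([sim_dm_gene(rng, 3, 8, 2000, 1e5, [pi_a] * 8),
                       sim_dm_gene(rng, 3, 8, 2000, 1e5, [pi_b] * 8)])
        labels = np.array(["a"] * 8 + ["b"] * 8)
        fit = fit_dm_gene(x, labels)
        ft = feature_level_test(fit, x, labels, group_of_interest="a")
        assert fit.p_value < 1e-6
        assert ft["p_value"][2] > 0.1
        assert abs(ft["effect"][2]) < 0.02

    def test_effect_sign_matches_usage_difference(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.integers(0, 100, size=(6, 3)) + 1
            labels = np.array(["a", "b"] * 3)
            fit = fit_dm_gene(x, labels)
            ft = feature_level_test(fit, x, labels, group_of_interest="a")
            u = x / x.sum(axis=1, keepdims=True)
            diff = u[labels == "a"].mean(axis=0) - u[labels == "b"].mean(axis=0)
            assert np.allclose(np.sign(ft["effect"]), np.sign(diff))

    def test_all_zero_isoform_is_flat(self):
        x = np.array([[50, 50, 0], [40, 60, 0], [55, 45, 0], [52, 48, 0]])
        labels = np.array(["a", "a", "b", "b"])
        fit = fit_dm_gene(x, labels)
        ft = feature_level_test(fit, x, labels)
        assert ft["p_value"][2] == 1.0
        assert ft["effect"][2] == 0.0


class TestScan:
    def _pb(self, counts, groups):
        units = pd.DataFrame({"group": groups},
                             index=[f"u{i}" for i in range(len(groups))])
        iso = pd.Index([f"i{j}" for j in range(counts.shape[1])])
        return PseudobulkMatrix(units, iso, counts)

    def _catalog(self, n_genes, J=2):
        rows = []
        for g in range(n_genes):
            for j in range(J):
                rows.append(dict(isoform_id=f"i{g * J + j}", gene_id=f"g{g}"))
        return make_catalog(rows)

    def test_single_group_contrast_is_error(self):
        cat = self._catalog(2)
        pb = self._pb(np.ones((3, 4), int) * 10, ["a", "a", "a"])
        with pytest.raises(ContrastError):
            run_usage_scan(pb, cat, ["a", "a", "a"])

    def test_group_without_units_is_error(self):
        cat = self._catalog(2)
        pb = self._pb(np.ones((3, 4), int) * 10, ["a", "a", None])
        with pytest.raises(ContrastError):
            run_usage_scan(pb, cat, ["a", "a", None])

    def test_padj_dominates_raw_p_and_directions_consistent(self):
        rng = np.random.default_rng(6)
        counts = rng.integers(1, 300, size=(8, 40))
        cat = self._catalog(20)
        groups = ["a"] * 4 + ["b"] * 4
        scan = run_usage_scan(self._pb(counts, groups), cat, groups,
                              group_of_interest="a")
        assert (scan.gene_table["padj"] >= scan.gene_table["p_value"] - 1e-12).all()
        it = scan.isoform_table
        high = it["direction"] == "high usage"
        assert (it.loc[high, "effect"] >= 0).all()
        assert (it.loc[~high, "effect"] <= 0).all()
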