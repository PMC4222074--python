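"""Driver filters, correlation modules, sparse CCA and ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats

from dgsearch.drivers import (DriverCandidate, DriverModule,
                              cna_expression_filter, filter_variable_features,
                              initial_modules, pairwise_driver_correlation,
                              rank_and_select_drivers, refine_module_scca,
                              refine_modules, target_count_curve)


def frame(rows, prefix="s"):
    rows = {k: np.asarray(v, dtype=float) for k, v in rows.items()}
    n = len(next(iter(rows.values())))
    return pd.DataFrame(rows, index=[f"{prefix}{i}" for i in range(n)]).T


class TestVariabilityFilter:
    def test_constant_feature_removed(self):
        expr = frame({"flat": [1.0] * 5, "var": [0, 1, 2, 1, 0]})
        kept = filter_variable_features(expr)
        assert "flat" not in kept and "var" in kept

    def test_two_subject_sd_kept(self):
        # SD of (-0.5, 0.5) with ddof=1 is ~0.707 >= 0.25
        expr = frame({"g": [-0.5, 0.5]})
        assert "g" in filter_variable_features(expr)

    def test_zero_threshold_keeps_everything(self):
        expr = frame({"a": [1.0, 1.0], "b": [0.0, 5.0]})
        assert list(filter_variable_features(expr, 0.0)) == ["a", "b"]


class TestCnaExpressionFilter:
    def test_separated_groups_retained(self):
        vals = pd.Series([2.0] * 10 + [0.0] * 40,
                         index=[f"s{i}" for i in range(50)])
        cand = cna_expression_filter(vals, [f"s{i}" for i in range(10)],
                                     "amp_only")
        assert cand.retained
        assert cand.fold_change == pytest.approx(4.0)
        assert cand.welch_p < 1e-6
        assert cand.consistency_fraction == 1.0

    def test_identical_means_give_half_p_and_rejection(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 20)
        vals = pd.Series(np.concatenate([base, base]),
                         index=[f"s{i}" for i in range(40)])
        cand = cna_expression_filter(vals, [f"s{i}" for i in range(20)],
                                     "amp_only")
        assert cand.welch_p == pytest.approx(0.5)
        assert not cand.retained

    def test_fold_change_rule_differs_for_genes_and_mirnas(self):
        # mean log2 difference 0.8 -> fold change 2^0.8 ~ 1.74 < 2
        rng = np.random.default_rng(1)
        alt = 0.8 + rng.normal(0, 0.05, 15)
        neu = rng.normal(0, 0.05, 45)
        vals = pd.Series(np.concatenate([alt, neu]),
                         index=[f"s{i}" for i in range(60)])
        altered = [f"s{i}" for i in range(15)]
        gene = cna_expression_filter(vals, altered, "amp_only",
                                     min_fold_change=2.0)
        assert not gene.retained and "fold_change" in gene.reason
        assert gene.fold_change == pytest.approx(2 ** 0.8, rel=0.1)
        mirna = cna_expression_filter(vals, altered, "amp_only",
                                      p_max=0.01, min_fold_change=None)
        assert mirna.retained

    def test_deletion_polarity_uses_lower_tail(self):
        vals = pd.Series([-2.0] * 10 + [0.0] * 40,
                         index=[f"s{i}" for i in range(50)])
        cand = cna_expression_filter(vals, [f"s{i}" for i in range(10)],
                                     "del_only")
        assert cand.retained
        assert cand.effect_fold_change == pytest.approx(4.0)

    def test_small_altered_group_rejected_with_reason(self):
        vals = pd.Series([2.0, 0.0, 0.0, 0.0],
                         index=[f"s{i}" for i in range(4)])
        cand = cna_expression_filter(vals, ["s0"], "amp_only")
        assert not cand.retained and cand.reason == "insufficient_data"

    def test_consistency_counts_matching_signs(self):
        vals = pd.Series([2.0] * 8 + [-0.1, -0.2] + [0.0] * 40,
                         index=[f"s{i}" for i in range(50)])
        cand = cna_expression_filter(vals, [f"s{i}" for i in range(10)],
                                     "amp_only", min_consistency=0.9)
        assert cand.consistency_fraction == pytest.approx(0.8)
        assert not cand.retained and "consistency" in cand.reason


class TestPairwiseCorrelation:
    def test_exact_copy_and_negation(self):
        rng = np.random.default_rng(2)
        d = rng.normal(size=20)
        expr = frame({"drv": d, "same": d, "neg": -d})
        r, p = pairwise_driver_correlation(expr, ["drv"], ["same", "neg"])
        assert r.at["drv", "same"] == pytest.approx(1.0)
        assert r.at["drv", "neg"] == pytest.approx(-1.0)
        assert p.at["drv", "same"] < 1e-10

    def test_t_transform_matches_permutation_p(self):
        rng = np.random.default_rng(3)
        n = 20
        d = rng.normal(size=n)
        t = 0.8 * d + rng.normal(size=n) * 0.6
        expr = frame({"drv": d, "tgt": t})
        r, p = pairwise_driver_correlation(expr, ["drv"], ["tgt"])
        robs = r.at["drv", "tgt"]
        texp = robs * np.sqrt((n - 2) / (1 - robs**2))
        assert p.at["drv", "tgt"] == pytest.approx(
            2 * stats.t.sf(abs(texp), df=n - 2))
        # permutation cross-check of the analytic p-value
        perms = 2000
        count = 0
        for k in range(perms):
            rp = np.corrcoef(d, rng.permutation(t))[0, 1]
            count += abs(rp) >= abs(robs)
        p_perm = (1 + count) / (perms + 1)
        assert abs(p_perm - p.at["drv", "tgt"]) < 0.02

    def test_zero_variance_feature_reported_missing(self):
        expr = frame({"drv": [1, 2, 3, 4, 5], "flat": [1, 1, 1, 1, 1]})
        r, p = pairwise_driver_correlation(expr, ["drv"], ["flat"])
        assert np.isnan(r.at["drv", "flat"])
        assert np.isnan(p.at["drv", "flat"])


class TestInitialModules:
    def test_strongest_significant_driver_wins(self):
        r = pd.DataFrame({"t": [0.9, 0.5]}, index=["A", "B"])
        p = pd.DataFrame({"t": [1e-5, 1e-4]}, index=["A", "B"])
        assert initial_modules(r, p)["A"] == ["t"]

    def test_insignificant_best_stays_unassigned(self):
        r = pd.DataFrame({"t": [0.9, 0.5]}, index=["A", "B"])
        p = pd.DataFrame({"t": [0.01, 0.02]}, index=["A", "B"])
        mods = initial_modules(r, p)
        assert mods["A"] == [] and mods["B"] == []

    def test_exact_tie_breaks_lexicographically(self):
        r = pd.DataFrame({"t": [0.7, 0.7]}, index=["B", "A"])
        p = pd.DataFrame({"t": [1e-5, 1e-5]}, index=["B", "A"])
        mods = initial_modules(r, p)
        assert mods["A"] == ["t"] and mods["B"] == []

    def test_assigned_targets_form_partition(self):
        rng = np.random.default_rng(4)
        r = pd.DataFrame(rng.uniform(-1, 1, (3, 30)),
                         index=["A", "B", "C"])
        p = pd.DataFrame(rng.uniform(0, 0.0005, (3, 30)),
                         index=["A", "B", "C"])
        mods = initial_modules(r, p)
        assigned = [t for ts in mods.values() for t in ts]
        assert len(assigned) == len(set(assigned)) == 30


class TestSparseCca:
    def test_identical_single_features_give_unit_correlation(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(30, 1))
        res = refine_module_scca(x, x.copy())
        assert res.corr == pytest.approx(1.0, abs=1e-8)
        assert abs(res.x_weights[0]) == pytest.approx(1.0)

    def test_zero_penalty_matches_classical_cca(self):
        # oracle: closed-form CCA as the top singular value of the whitened
        # cross-covariance, computed independently with scipy
        rng = np.random.default_rng(6)
        for _ in range(50):
            n = int(rng.integers(30, 60))
            p = int(rng.integers(2, 6))
            q = int(rng.integers(2, 7))
            X = rng.normal(size=(n, p))
            Y = rng.normal(size=(n, q))
            res = refine_module_scca(X, Y)
            Xc = X - X.mean(0)
            Yc = Y - Y.mean(0)
            Cxx = Xc.T @ Xc / (n - 1)
            Cyy = Yc.T @ Yc / (n - 1)
            Cxy = Xc.T @ Yc / (n - 1)
            K = linalg.solve(linalg.sqrtm(Cxx), Cxy) @ \
                linalg.inv(linalg.sqrtm(Cyy))
            rho = linalg.svdvals(np.real(K))[0]
            assert res.corr == pytest.approx(rho, abs=1e-6)

    def test_strong_penalty_recovers_planted_support(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n = 80
            d = rng.normal(size=n)
            X = d[:, None]
            Y = np.concatenate(
                [np.tile(d, (5, 1)).T + 0.2 * rng.normal(size=(n, 5)),
                 rng.normal(size=(n, 50))], axis=1)
            res = refine_module_scca(X, Y, penalty_y=0.3)
            support = set(np.flatnonzero(np.abs(res.y_weights) > 0))
            hits += support == set(range(5))
        assert hits >= 18

    def test_unpenalized_target_side_keeps_every_target(self):
        rng = np.random.default_rng(7)
        expr = pd.DataFrame(rng.normal(size=(6, 40)),
                            index=["drv"] + [f"t{i}" for i in range(5)],
                            columns=[f"s{i}" for i in range(40)])
        mods = refine_modules(expr, {"drv": [f"t{i}" for i in range(5)]},
                              penalty_y=None)
        assert mods["drv"].targets == [f"t{i}" for i in range(5)]


class TestRankAndSelect:
    def _cand(self, feature, fc, p):
        return DriverCandidate(feature=feature, region_index=0,
                               polarity="amp_only", fold_change=fc,
                               welch_p=p, consistency_fraction=1.0,
                               retained=True)

    def _module(self, driver, n):
        return DriverModule(driver=driver, targets=[f"t{i}" for i in
                                                    range(n)])

    def test_final_thresholds_applied(self):
        cands = [self._cand("big", 5.0, 1e-4),
                 self._cand("weak_fc", 3.5, 1e-6),
                 self._cand("weak_p", 6.0, 0.01)]
        mods = {c.feature: self._module(c.feature, 10) for c in cands}
        final = rank_and_select_drivers(cands, mods)
        assert [c.feature for c in final] == ["big"]

    def test_ordering_by_module_size_then_fold_change(self):
        cands = [self._cand("a", 5.0, 1e-4), self._cand("b", 8.0, 1e-4),
                 self._cand("c", 6.0, 1e-4)]
        mods = {"a": self._module("a", 100), "b": self._module("b", 100),
                "c": self._module("c", 500)}
        final = rank_and_select_drivers(cands, mods)
        assert [c.feature for c in final] == ["c", "b", "a"]


class TestTargetCountCurve:
    def _module(self, rs):
        targets = [f"t{i}" for i in range(len(rs))]
        return DriverModule(driver="d", targets=targets,
                            target_corr=dict(zip(targets, rs)))

    def test_zero_cutoff_counts_whole_module(self):
        mod = self._module([0.2, 0.5, 0.9])
        counts, _ = target_count_curve(mod, [0.0, 1.0])
        assert counts[0.0] == 3
        assert counts[1.0] == 0

    def test_counts_non_increasing_on_random_modules(self):
        rng = np.random.default_rng(8)
        grid = np.round(np.linspace(0, 1, 11), 2)
        for _ in range(100):
            mod = self._module(rng.uniform(-1, 1,
                                           size=rng.integers(1, 40)))
            counts, _ = target_count_curve(mod, grid)
            seq = [counts[t] for t in grid]
            assert all(a >= b for a, b in zip(seq[:-1], seq[1:]))

    def test_smallest_cutoff_reaching_requested_size(self):
        # counts over the grid are (610, 250, 120, 80): only the top
        # cutoff brings the module to <= 100 targets
        rs = [0.35] * 360 + [0.45] * 130 + [0.55] * 40 + [0.62] * 80
        mod = self._module(rs)
        counts, cutoff = target_count_curve(
            mod, [0.3, 0.4, 0.5, 0.6], desired_size=100)
        assert counts[0.3] == 610 and counts[0.4] == 250
        assert counts[0.5] == 120 and counts[0.6] == 80
        assert cutoff == 0.6
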