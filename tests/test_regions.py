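"""Recurrent-region discovery, polarity, ANOVA and cluster merging."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from dgsearch.exceptions import ConfigurationError
from dgsearch.regions import (RecurrentRegion, anova_differential_regions,
                              classify_polarity, find_recurrent_regions,
                              map_features_to_regions, merge_into_clusters)
from dgsearch.segmentation import CnaCall


def call(chrom, start, end, state="gain", n_probes=10, mean=None):
    if mean is None:
        mean = 0.5 if state in ("gain", "amplification") else -0.5
    return CnaCall(chrom, start, end, n_probes, mean, state=state)


def brute_force_regions(calls, min_recurrence):
    """Per-base scan oracle on small integer genomes (closed call coords)."""
    eligible = [s for s, cs in calls.items() if cs]
    if not eligible:
        return []
    denom = len(eligible)
    regions = []
    chroms = sorted({c.chrom for cs in calls.values() for c in cs})
    for chrom in chroms:
        events = [(c.start, c.end, s, "del" if c.state == "loss" else "dup")
                  for s, cs in calls.items() for c in cs if c.chrom == chrom]
        if not events:
            continue
        lo = min(e[0] for e in events)
        hi = max(e[1] for e in events)
        prev_state, run_start = None, None
        for base in range(lo, hi + 2):
            state = {s: st for a, b, s, st in events if a <= base <= b}
            state = state or None
            if state != prev_state:
                if prev_state is not None:
                    regions.append((chrom, run_start, base,
                                    prev_state,
                                    len(prev_state) / denom))
                run_start = base
                prev_state = state
    return [r for r in regions if r[4] >= min_recurrence]


class TestFindRecurrentRegions:
    def test_ten_percent_threshold_retains_and_drops(self):
        # 12 of 121 eligible subjects retained at 10%; 11 of 121 dropped
        calls = {}
        for i in range(12):
            calls[f"A{i:03d}"] = [call("1", 100, 200)]
        for i in range(11):
            calls[f"B{i:03d}"] = [call("2", 100, 200)]
        for i in range(98):
            calls[f"C{i:03d}"] = [call("3", 100 + i * 10, 101 + i * 10)]
        regions = find_recurrent_regions(calls, min_recurrence=0.10)
        spans = {(r.chromosome, r.n_altered) for r in regions}
        assert ("1", 12) in spans
        assert not any(r.chromosome == "2" for r in regions)

    def test_identical_calls_give_single_full_recurrence_region(self):
        calls = {f"S{i}": [call("1", 100, 500)] for i in range(5)}
        regions = find_recurrent_regions(calls)
        assert len(regions) == 1
        assert regions[0].recurrence == 1.0
        assert (regions[0].start, regions[0].end_excl) == (100, 501)

    def test_empty_call_set_gives_empty_result(self):
        assert find_recurrent_regions({"S0": []}) == []

    def test_matches_per_base_brute_force_oracle(self):
        rng = np.random.default_rng(10)
        for trial in range(100):
            calls = {}
            n_subj = int(rng.integers(2, 7))
            for i in range(n_subj):
                subj_calls = []
                cursor = 0
                while cursor < 450 and rng.random() < 0.8:
                    start = cursor + int(rng.integers(1, 60))
                    end = start + int(rng.integers(0, 80))
                    if end >= 500:
                        break
                    state = "gain" if rng.random() < 0.6 else "loss"
                    subj_calls.append(call("1", start, end, state))
                    cursor = end + 1
                calls[f"S{i}"] = subj_calls
            if not any(calls.values()):
                continue
            got = find_recurrent_regions(calls, min_recurrence=0.0)
            expected = brute_force_regions(calls, 0.0)
            got_t = [(r.chromosome, r.start, r.end_excl, r.states,
                      r.recurrence) for r in got]
            assert got_t == expected, f"trial {trial}"

    def test_recurrence_invariant_to_subject_order_and_call_splitting(self):
        calls = {"S0": [call("1", 100, 200)],
                 "S1": [call("1", 100, 200)],
                 "S2": [call("1", 150, 250)]}
        base = find_recurrent_regions(calls, 0.0)
        reordered = find_recurrent_regions(dict(reversed(calls.items())), 0.0)
        assert [(r.start, r.end_excl, r.recurrence) for r in base] == \
            [(r.start, r.end_excl, r.recurrence) for r in reordered]
        # split S0's call into two abutting calls of the same state
        split = dict(calls)
        split["S0"] = [call("1", 100, 150), call("1", 151, 200)]
        resplit = find_recurrent_regions(split, 0.0)
        assert [(r.start, r.end_excl, r.recurrence) for r in base] == \
            [(r.start, r.end_excl, r.recurrence) for r in resplit]


class TestClassifyPolarity:
    def _region(self, n_dup, n_del):
        states = {f"D{i}": "dup" for i in range(n_dup)}
        states.update({f"L{i}": "del" for i in range(n_del)})
        return RecurrentRegion("1", 0, 100, states, 0.5)

    def test_pure_duplications_strict(self):
        assert classify_polarity(self._region(10, 0), 0.0) == "amp_only"

    def test_small_mixture_allowed_at_ten_percent(self):
        # 1 of 20 = 5% mixture < 10%
        assert classify_polarity(self._region(19, 1), 0.10) == "amp_only"

    def test_any_mixture_violates_strict_mode(self):
        assert classify_polarity(self._region(19, 1), 0.0) == "mixed"

    def test_mixture_at_tolerance_is_mixed(self):
        # 2 of 20 = 10%, not strictly below the tolerance
        assert classify_polarity(self._region(18, 2), 0.10) == "mixed"

    def test_bad_tolerance_rejected(self):
        with pytest.raises(ConfigurationError):
            classify_polarity(self._region(5, 0), 0.6)


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        mat = pd.DataFrame([[1.0] * 9], index=["r"],
                           columns=[f"s{i}" for i in range(9)])
        labels = pd.Series(["AC"] * 3 + ["SCC"] * 3 + ["LCC"] * 3,
                           index=mat.columns)
        res = anova_differential_regions(mat, labels)
        assert res.loc["r", "F"] == 0.0

    def test_separated_groups_give_tiny_p(self):
        rng = np.random.default_rng(11)
        vals = np.concatenate([np.zeros(3), np.ones(3), 2 * np.ones(3)])
        vals = vals + rng.normal(0, 1e-6, 9)
        mat = pd.DataFrame([vals], index=["r"],
                           columns=[f"s{i}" for i in range(9)])
        labels = pd.Series(["AC"] * 3 + ["SCC"] * 3 + ["LCC"] * 3,
                           index=mat.columns)
        res = anova_differential_regions(mat, labels)
        assert res.loc["r", "p"] < 1e-10

    def test_bh_adjustment_matches_hand_computation(self):
        # BH of [0.01, 0.02, 0.03] -> [0.03, 0.03, 0.03]
        adj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_group_smaller_than_two_reported_missing(self):
        mat = pd.DataFrame([[0.0, 0.1, 1.0, 1.1, 2.0]], index=["r"],
                           columns=[f"s{i}" for i in range(5)])
        labels = pd.Series(["AC", "AC", "SCC", "SCC", "LCC"],
                           index=mat.columns)
        res = anova_differential_regions(mat, labels)
        # LCC has one subject: the test runs on the two usable groups
        assert np.isfinite(res.loc["r", "p"])
        mat2 = mat[["s0", "s1", "s4"]]
        res2 = anova_differential_regions(mat2, labels[["s0", "s1", "s4"]])
        assert np.isnan(res2.loc["r", "p"])


class TestMergeClusters:
    def _region(self, chrom, start, end):
        return RecurrentRegion(chrom, start, end, {"S0": "dup"}, 0.5)

    def _freq(self, scc_gain):
        return pd.DataFrame(
            {"AC": [10.0, 0.0], "SCC": [scc_gain, 0.0], "LCC": [0.0, 0.0]},
            index=["dup", "del"])

    def test_identical_tables_merge(self):
        regions = [self._region("1", 0, 100), self._region("1", 100, 200)]
        clusters = merge_into_clusters(regions,
                                       [self._freq(20), self._freq(20)])
        assert len(clusters) == 1
        assert clusters[0].end_excl == 200

    def test_two_point_difference_splits(self):
        regions = [self._region("1", 0, 100), self._region("1", 100, 200)]
        clusters = merge_into_clusters(regions,
                                       [self._freq(20), self._freq(22)])
        assert len(clusters) == 2

    def test_different_chromosomes_never_merge(self):
        regions = [self._region("1", 0, 100), self._region("2", 100, 200)]
        clusters = merge_into_clusters(regions,
                                       [self._freq(20), self._freq(20)])
        assert len(clusters) == 2

    def test_tolerance_anchored_to_first_region(self):
        # drifting by 0.8 points each region: the third is 1.6 from the
        # anchor and starts a new cluster even though each adjacent step
        # is within tolerance
        regions = [self._region("1", i * 100, (i + 1) * 100)
                   for i in range(3)]
        freqs = [self._freq(20), self._freq(20.8), self._freq(21.6)]
        clusters = merge_into_clusters(regions, freqs, tolerance=1.0)
        assert [len(c.members) for c in clusters] == [2, 1]


class TestMapFeatures:
    def _regions(self):
        return [RecurrentRegion("1", 150, 300, {"S0": "dup"}, 1.0)]

    def test_overlap_assigned(self):
        ann = pd.DataFrame({"chrom": ["1"], "start": [100], "end": [200]},
                           index=["g1"])
        assert map_features_to_regions(self._regions(), ann)[0] == ["g1"]

    def test_half_open_abutment_not_assigned(self):
        ann = pd.DataFrame({"chrom": ["1"], "start": [300], "end": [400]},
                           index=["g1"])
        assert map_features_to_regions(self._regions(), ann)[0] == []

    def test_gene_spanning_two_regions_assigned_to_both(self):
        regions = [RecurrentRegion("1", 100, 200, {"S0": "dup"}, 1.0),
                   RecurrentRegion("1", 200, 300, {"S0": "dup"}, 1.0)]
        ann = pd.DataFrame({"chrom": ["1"], "start": [150], "end": [250]},
                           index=["g1"])
        mapped = map_features_to_regions(regions, ann)
        assert mapped[0] == ["g1"] and mapped[1] == ["g1"]

    def test_unknown_chromosome_warns_and_skips(self):
        ann = pd.DataFrame({"chrom": ["1", "7"], "start": [100, 100],
                            "end": [200, 200]}, index=["g1", "g2"])
        with pytest.warns(UserWarning):
            mapped = map_features_to_regions(self._regions(), ann)
        assert mapped[0] == ["g1"]
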