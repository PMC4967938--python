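import itertools
import math

import numpy as np
import pytest

from pathconcord import (chance_expectation, chi_squared_test, compare_all,
                         compare_pair, consistent_core_genes,
                         contingency_table, delta_over_chance,
                         predictive_values, shared_regulation)

from conftest import make_profile


class TestPredictiveValues:
    def test_hand_enumeration(self, ten_pathways):
        p1 = make_profile(ten_pathways, up=["P1", "P2", "P5"], down=["P6", "P7"])
        p2 = make_profile(ten_pathways, up=["P1", "P2", "P3", "P4"],
                          down=["P6", "P8"])
        ppv, npv, mean_pv = predictive_values(p1, p2)
        assert ppv == pytest.approx(2 / 4)
        assert npv == pytest.approx(1 / 2)
        assert mean_pv == pytest.approx(0.5)

    def test_self_comparison_is_perfect(self, ten_pathways):
        p = make_profile(ten_pathways, up=["P1"], down=["P2"])
        assert predictive_values(p, p) == (1.0, 1.0, 1.0)

    def test_disjoint_regulation_is_zero(self, ten_pathways):
        p1 = make_profile(ten_pathways, up=["P1"], down=["P2"])
        p2 = make_profile(ten_pathways, up=["P3"], down=["P4"])
        assert predictive_values(p1, p2) == (0.0, 0.0, 0.0)

    def test_zero_denominator_undefined(self, ten_pathways):
        p1 = make_profile(ten_pathways, up=["P1"], down=["P2"])
        p2 = make_profile(ten_pathways, up=[], down=["P2"])
        ppv, npv, mean_pv = predictive_values(p1, p2)
        assert math.isnan(ppv)
        assert npv == 1.0 and mean_pv == 1.0  # only the defined side averaged


class TestChanceExpectation:
    def test_ten_percent_base_rate(self):
        pathways = [f"P{i}" for i in range(1, 101)]
        p1 = make_profile(pathways, up=[f"P{i}" for i in range(1, 11)])
        e_ppv, e_npv = chance_expectation(p1)
        assert e_ppv == pytest.approx(0.10)
        assert e_npv == 0.0

    def test_monte_carlo_shuffle_agrees(self, ten_pathways):
        pathways = [f"P{i}" for i in range(1, 41)]
        p1 = make_profile(pathways, up=[f"P{i}" for i in range(1, 9)],
                          down=[f"P{i}" for i in range(9, 15)])
        p2 = make_profile(pathways, up=[f"P{i}" for i in range(5, 15)],
                          down=[f"P{i}" for i in range(20, 26)])
        e_ppv, _ = chance_expectation(p1)
        rng = np.random.default_rng(17)
        states2 = p2.states.values.copy()
        ppvs = []
        up1 = p1.up_set()
        for _ in range(2000):
            s = rng.permutation(states2)
            up2 = {pw for pw, st in zip(p2.states.index, s) if st == "up"}
            ppvs.append(len(up1 & up2) / len(up2))
        se = np.std(ppvs, ddof=1) / np.sqrt(len(ppvs))
        assert abs(np.mean(ppvs) - e_ppv) < 3 * se


class TestDeltaOverChance:
    def test_percentage_points(self):
        assert delta_over_chance((0.61, 0.61), (0.26, 0.26)) == pytest.approx(35.0)

    def test_zero_when_at_chance(self):
        assert delta_over_chance((0.3, 0.2), (0.3, 0.2)) == 0.0

    def test_undefined_side_skipped(self):
        assert delta_over_chance((math.nan, 0.5), (0.1, 0.3)) == pytest.approx(20.0)


class TestContingencyAndChi2:
    def test_identical_profiles_diagonal(self, ten_pathways):
        p = make_profile(ten_pathways, up=["P1", "P2"], down=["P3"])
        table = contingency_table(p, p)
        assert table.sum() == len(ten_pathways)
        assert np.all(table == np.diag([2, 1, 7]))

    def test_hand_enumerated_toy(self, ten_pathways):
        p1 = make_profile(ten_pathways, up=["P1", "P2", "P5"], down=["P6", "P7"])
        p2 = make_profile(ten_pathways, up=["P1", "P2", "P3", "P4"],
                          down=["P6", "P8"])
        expected = np.array([[2, 0, 1],    # P1,P2 | - | P5
                             [0, 1, 1],    # - | P6 | P7
                             [2, 1, 2]])   # P3,P4 | P8 | P9,P10
        np.testing.assert_array_equal(contingency_table(p1, p2), expected)

    def test_diagonal_table_statistic(self):
        stat, df, p = chi_squared_test(np.diag([10, 10, 10]))
        assert stat == pytest.approx(60.0)
        assert df == 4

    def test_proportional_rows_independent(self):
        stat, df, p = chi_squared_test(np.array([[2, 4, 6], [1, 2, 3],
                                                 [3, 6, 9]]))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_textbook_oracle_on_random_tables(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            table = rng.integers(1, 25, size=(3, 3))
            stat, df, _ = chi_squared_test(table)
            expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
            oracle = ((table - expected) ** 2 / expected).sum()
            assert stat == pytest.approx(oracle, abs=1e-10)
            assert df == 4

    def test_zero_margin_dropped_with_df_adjust(self):
        table = np.array([[5, 3, 0], [2, 8, 0], [4, 4, 0]])
        stat, df, p = chi_squared_test(table)
        assert df == 2  # 3x2 after dropping the empty column

    def test_degenerate_single_cell(self):
        stat, df, p = chi_squared_test(np.array([[7, 0, 0], [0, 0, 0],
                                                 [0, 0, 0]]))
        assert (stat, df, p) == (0.0, 0, 1.0)


class TestCompareAll:
    def make_cohort(self, n_h, n_m, pathways, rng):
        profiles, species = [], {}
        for i in range(n_h + n_m):
            regulated = rng.choice(pathways, size=10, replace=False)
            prof = make_profile(pathways, up=regulated[:6], down=regulated[6:],
                                dataset_id=f"d{i:02d}")
            profiles.append(prof)
            species[prof.dataset_id] = "human" if i < n_h else "mouse"
        return profiles, species

    def test_pair_counts_by_species_group(self, ten_pathways):
        pathways = [f"P{i}" for i in range(1, 31)]
        rng = np.random.default_rng(1)
        profiles, species = self.make_cohort(8, 9, pathways, rng)
        pairs, groups, counts = compare_all(profiles, species)
        assert len(pairs) == 136  # C(17,2); self-pairs excluded
        sizes = pairs.groupby("species_pair").size()
        assert sizes["human-human"] == 28
        assert sizes["mouse-mouse"] == 36
        assert sizes["human-mouse"] == 72

    def test_order_invariance(self, ten_pathways):
        pathways = [f"P{i}" for i in range(1, 31)]
        rng = np.random.default_rng(2)
        profiles, species = self.make_cohort(2, 2, pathways, rng)
        pairs_fwd, _, _ = compare_all(profiles, species)
        pairs_rev, _, _ = compare_all(list(reversed(profiles)), species)
        assert pairs_fwd.equals(pairs_rev)

    def test_mean_pv_direction_symmetric(self, ten_pathways):
        p1 = make_profile(ten_pathways, up=["P1", "P2"], down=["P3"],
                          dataset_id="a")
        p2 = make_profile(ten_pathways, up=["P1", "P4", "P5"], down=["P3"],
                          dataset_id="b")
        r12 = compare_pair(p1, p2)
        r21 = compare_pair(p2, p1)
        assert r12.mean_pv == pytest.approx(r21.mean_pv)
        assert r12.chi2_stat == pytest.approx(r21.chi2_stat)

    def test_planted_identity_pair_significant(self, ten_pathways):
        pathways = [f"P{i}" for i in range(1, 96)]
        regulated = pathways[:30]
        p1 = make_profile(pathways, up=regulated[:15], down=regulated[15:],
                          dataset_id="a")
        p2 = make_profile(pathways, up=regulated[:15], down=regulated[15:],
                          dataset_id="b")
        res = compare_pair(p1, p2)
        assert res.mean_pv == 1.0 and res.significant


class TestChi2NullRejection:
    def test_rejection_rate_under_shuffled_profiles(self):
        # independence null: shuffling one profile's states should reject
        # at about the nominal 5% level
        rng = np.random.default_rng(42)
        states1 = rng.permutation(["up"] * 28 + ["down"] * 28 + ["null"] * 39)
        states2 = np.array(["up"] * 30 + ["down"] * 25 + ["null"] * 40)
        idx = {"up": 0, "down": 1, "null": 2}
        rows = [idx[s] for s in states1]
        rejections = 0
        n_shuffles = 500
        for _ in range(n_shuffles):
            cols = [idx[s] for s in rng.permutation(states2)]
            table = np.zeros((3, 3), dtype=int)
            np.add.at(table, (rows, cols), 1)
            _, _, p = chi_squared_test(table)
            rejections += p <= 0.05
        rate = rejections / n_shuffles
        se = math.sqrt(0.05 * 0.95 / n_shuffles)
        assert abs(rate - 0.05) < 3 * se


class TestSharedRegulation:
    def test_shared_requires_consistent_sign_everywhere(self, ten_pathways):
        p1 = make_profile(ten_pathways, up=["P1", "P2"], down=["P3"],
                          dataset_id="a")
        p2 = make_profile(ten_pathways, up=["P1"], down=["P2", "P3"],
                          dataset_id="b")
        matrix, shared = shared_regulation([p1, p2])
        assert shared == ["P1", "P3"]  # P2 flips sign between datasets
        assert matrix.shape == (10, 2)

    def test_blanks_exactly_where_state_null(self, ten_pathways):
        p1 = make_profile(ten_pathways, up=["P1"], down=["P2"], dataset_id="a")
        matrix, _ = shared_regulation([p1])
        blank = matrix["a"].isna()
        assert set(matrix.index[~blank]) == {"P1", "P2"}

    def test_empty_subgroup_rejected(self):
        with pytest.raises(ValueError, match="empty subgroup"):
            shared_regulation([])


class TestConsistentCoreGenes:
    def make_results(self, tallies, n_datasets=11):
        import pandas as pd
        results = {}
        for d in range(n_datasets):
            genes = [g for g, k in tallies.items() if d < k]
            results[f"ds{d}"] = pd.DataFrame([dict(
                set="TLR", size=20, es=0.5, nes=2.0, p_nominal=0.001,
                q_fdr=0.01, leading_edge=",".join(genes), status="tested")])
        return results

    def test_threshold_inclusion_and_sorting(self):
        results = self.make_results({"CD14": 11, "LBP": 9, "TLR2": 8})
        out = consistent_core_genes(results, "TLR", k_min=9)
        assert list(out["gene"]) == ["CD14", "LBP"]
        assert list(out["n_leading_edges"]) == [11, 9]

    def test_requires_enough_tested_datasets(self):
        results = self.make_results({"CD14": 3}, n_datasets=3)
        with pytest.raises(ValueError, match="need >= 9"):
            consistent_core_genes(results, "TLR", k_min=9)
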