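"""Combined-state model: universe, tests, BH, classification, scans."""


import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from duoqtl.integrate import CommonMarkerTable
from duoqtl.qtl_combined import (GROUPS, assign_states, bh_adjust,
                                 classify_pair, classify_qtl, combined_scan,
                                 enumerate_states, pairwise_state_tests)
from duoqtl.simulate import (mechanism_phenotype, plant_indel_carriers,
                             simulate_marker_population)


class TestStateUniverse:
    def test_exactly_ten_states(self):
        states = enumerate_states()
        assert len(states) == 10
        assert len(set(states)) == 10

    def test_worked_example_member_and_impossible_label(self):
        states = enumerate_states()
        assert "D1.N1.1" in states
        assert "D1.N2.0" not in states  # no haplotype survives a deletion

    def test_structure_closes(self):
        """2 Pd haplotypes x (deleted + 2 Pn haplotypes x 2 doses)."""
        by_pd = {}
        for s in enumerate_states():
            by_pd.setdefault(s.split(".")[0], []).append(s)
        assert set(by_pd) == {"D1", "D2"}
        assert all(len(v) == 5 for v in by_pd.values())


class TestAssignStates:
    def _table(self, pd_v, pn_v, dose_v):
        markers = pd.DataFrame([["Chr01_1_10", "Chr01", 1, 10]],
                               columns=["marker_id", "chrom", "start", "end"])
        idx = pd.Index(markers["marker_id"], name="marker_id")
        return CommonMarkerTable(
            markers=markers,
            pd_hap=pd.DataFrame([[pd_v]], index=idx, columns=["L1"]),
            pn_hap=pd.DataFrame([[pn_v]], index=idx, columns=["L1"]),
            dose=pd.DataFrame([[dose_v]], index=idx, columns=["L1"],
                              dtype=float))

    @pytest.mark.parametrize("pd_v,pn_v,dose_v,expected", [
        ("D1", "N1", 1.0, "D1.N1.1"),
        ("D2", np.nan, 0.0, "D2.NA.0"),
        (np.nan, "N1", 1.0, None),     # incomplete combination
        ("D1", np.nan, 1.0, None),     # Pn missing at non-zero dose
        ("D1", "N2", np.nan, None),    # dose missing
    ])
    def test_assignment(self, pd_v, pn_v, dose_v, expected):
        st = assign_states(self._table(pd_v, pn_v, dose_v))
        got = st.states.iloc[0, 0]
        if expected is None:
            assert pd.isna(got)
        else:
            assert got == expected

    def test_dose_zero_with_pn_haplotype_is_invariant_violation(self):
        with pytest.raises(ValueError, match="dose 0"):
            assign_states(self._table("D1", "N2", 0.0))

    def test_assigned_states_stay_in_universe(self, marker_population):
        st = assign_states(marker_population.to_common_marker_table())
        universe = set(enumerate_states())
        vals = st.states.to_numpy().ravel()
        assert {v for v in vals if isinstance(v, str)} <= universe


class TestPairwiseStateTests:
    def _y_states(self, sizes, means, rng):
        states = enumerate_states()
        y, labels = [], []
        for (size, mean), s in zip(zip(sizes, means), states):
            y.extend(rng.normal(mean, 1.0, size))
            labels.extend([s] * size)
        idx = [f"L{i}" for i in range(len(y))]
        return pd.Series(y, index=idx), pd.Series(labels, index=idx)

    def test_all_states_present_gives_45_pairs(self):
        rng = np.random.default_rng(1)
        y, states = self._y_states([8] * 10, [0] * 10, rng)
        res = pairwise_state_tests(y, states, n_perm=20, seed=2)
        assert len(res) == 45

    def test_three_states_three_pairs(self):
        rng = np.random.default_rng(3)
        y, states = self._y_states([10, 10, 10], [0, 0, 0], rng)
        res = pairwise_state_tests(y, states, n_perm=20, seed=4)
        assert len(res) == 3

    def test_comparison_count_law(self):
        """Pairs tested == C(k, 2) for k qualifying states, always <= 45."""
        rng = np.random.default_rng(5)
        for k in (2, 4, 7, 10):
            y, states = self._y_states([6] * k, [0] * k, rng)
            res = pairwise_state_tests(y, states, n_perm=10, seed=6)
            assert len(res) == k * (k - 1) // 2 <= 45

    def test_small_groups_excluded(self):
        rng = np.random.default_rng(7)
        y, states = self._y_states([10, 10, 4], [0, 0, 0], rng)
        res = pairwise_state_tests(y, states, n_perm=10, min_group=5, seed=8)
        assert len(res) == 1

    def test_identical_groups_give_p_one(self):
        y = pd.Series([2.0] * 12, index=[f"L{i}" for i in range(12)])
        states = pd.Series(["D1.N1.1"] * 6 + ["D1.N2.1"] * 6, index=y.index)
        res = pairwise_state_tests(y, states, n_perm=99, seed=9)
        assert res["p_raw"].iloc[0] == 1.0

    def test_fewer_than_two_states_is_error(self):
        y = pd.Series(np.arange(8.0), index=[f"L{i}" for i in range(8)])
        states = pd.Series(["D1.N1.1"] * 8, index=y.index)
        with pytest.raises(ValueError, match="fewer than 2"):
            pairwise_state_tests(y, states, n_perm=10, seed=10)

    def test_strong_separation_detected(self):
        rng = np.random.default_rng(11)
        y, states = self._y_states([30, 30], [0, 3], rng)
        res = pairwise_state_tests(y, states, n_perm=200, seed=12)
        assert res["p_raw"].iloc[0] == pytest.approx(1 / 201)


class TestBhAdjust:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_monotone_after_sorting(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        assert (np.diff(adj[np.argsort(p)]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_matches_brute_force_and_statsmodels(self):
        """Step-up definition, brute force: p_adj(i) = min_{j>=i} p(j)m/j."""
        rng = np.random.default_rng(14)
        for _ in range(1000):
            m = rng.integers(1, 40)
            p = np.round(rng.uniform(size=m), 3)
            adj = bh_adjust(p)
            order = np.argsort(p, kind="stable")
            brute = np.empty(m)
            for rank, idx in enumerate(order, start=1):
                brute[idx] = min(min(p[order[j - 1]] * m / j
                                     for j in range(rank, m + 1)), 1.0)
            np.testing.assert_allclose(adj, brute, atol=1e-12)
            sm = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(adj, sm, atol=1e-12)


class TestClassification:
    @pytest.mark.parametrize("a,b,expected", [
        ("D1.N1.1", "D1.NA.0", "deletion"),
        ("D1.N1.1", "D1.N1.2", "insertion"),
        ("D1.NA.0", "D1.N1.2", "deletion+insertion"),
        ("D1.N1.1", "D2.N1.1", "Pd"),
        ("D1.N1.1", "D1.N2.1", "Pn"),
        ("D1.N1.1", "D2.N2.1", "Pd+Pn"),
        ("D1.N1.1", "D2.N2.2", None),   # dose and haplotype both differ
        ("D1.N1.1", "D2.NA.0", None),
        ("D1.NA.0", "D2.NA.0", "Pd"),
    ])
    def test_pair_typing(self, a, b, expected):
        assert classify_pair(a, b) == expected

    def _pairs(self, pairs):
        return pd.DataFrame(pairs, columns=["state_a", "state_b"])

    def test_union_of_dosage_evidence(self):
        both = self._pairs([("D1.N1.1", "D1.NA.0"), ("D1.N1.1", "D1.N1.2")])
        assert classify_qtl(both) == "deletion+insertion"

    def test_dosage_evidence_wins_over_allelic(self):
        mixed = self._pairs([("D1.N1.1", "D1.NA.0"), ("D1.N1.1", "D2.N1.1")])
        assert classify_qtl(mixed) == "deletion"

    def test_allelic_union(self):
        assert classify_qtl(self._pairs([("D1.N1.1", "D2.N1.1"),
                                         ("D1.N1.1", "D1.N2.1")])) == "Pd+Pn"

    def test_joint_pairs_do_not_override_single_mechanism(self):
        # cross pairs fire under a pure Pn effect; label stays Pn
        assert classify_qtl(self._pairs([("D1.N1.1", "D1.N2.1"),
                                         ("D1.N1.1", "D2.N2.1")])) == "Pn"
        # 0-vs-2 pairs fire under a pure deletion effect; label stays deletion
        assert classify_qtl(self._pairs([("D1.N1.1", "D1.NA.0"),
                                         ("D1.NA.0", "D1.N1.2")])) == "deletion"

    def test_lone_cross_pair_yields_joint_label(self):
        assert classify_qtl(self._pairs([("D1.N1.1", "D2.N2.1")])) == "Pd+Pn"
        assert classify_qtl(
            self._pairs([("D1.NA.0", "D1.N1.2")])) == "deletion+insertion"

    def test_only_untyped_pairs_is_ambiguous(self):
        assert classify_qtl(self._pairs([("D1.N1.1", "D2.N2.2")])) == "ambiguous"

    def test_six_canonical_groups(self):
        assert len(GROUPS) == 6


class TestCombinedScan:
    def test_null_trait_rarely_yields_qtls(self, marker_population):
        """Under the BH-controlled null most replicates yield no QTL."""
        pop = marker_population
        states = assign_states(pop.to_common_marker_table())
        rng = np.random.default_rng(41)
        hits = 0
        reps = 12
        for r in range(reps):
            y = pd.Series(rng.normal(size=len(pop.line_ids)),
                          index=pop.line_ids)
            res = combined_scan(y, states, n_perm=200, alpha=0.05,
                                seed=100 + r, trait="null")
            hits += int(len(res.qtls) > 0)
        assert hits <= 3

    def test_planted_deletion_classified_deletion(self):
        pop = simulate_marker_population(seed=51)
        plant_indel_carriers(pop, 30, "deletion", n_carriers=24, seed=52)
        y, _ = mechanism_phenotype(pop, 30, "deletion", effect_std=0.6,
                                   seed=53)
        states = assign_states(pop.to_common_marker_table())
        res = combined_scan(y, states, n_perm=500, alpha=0.05, seed=54,
                            trait="t")
        overlapping = res.qtls[
            res.qtls["start_marker"].str.startswith("Chr02")]
        assert len(overlapping) >= 1
        assert "deletion" in set(overlapping["channel_or_group"])

    def test_planted_pn_effect_classified_pn(self):
        pop = simulate_marker_population(seed=55)
        y, _ = mechanism_phenotype(pop, 30, "Pn", effect_std=0.6, seed=56)
        states = assign_states(pop.to_common_marker_table())
        res = combined_scan(y, states, n_perm=500, alpha=0.05, seed=57,
                            trait="t")
        overlapping = res.qtls[
            res.qtls["start_marker"].str.startswith("Chr02")]
        assert len(overlapping) >= 1
        assert "Pn" in set(overlapping["channel_or_group"])
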