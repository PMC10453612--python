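"""Differential expression, core gene groups, and overlap permutation tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import rescuekit as rk
from rescuekit import degs
from rescuekit.exceptions import InsufficientDataError, ParameterError


class TestBHAdjust:
    def test_hand_stepped_example(self):
        adj = degs.bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate_inputs(self):
        assert degs.bh_adjust([0.3])[0] == pytest.approx(0.3)
        np.testing.assert_allclose(degs.bh_adjust([1.0, 1.0, 1.0]), 1.0)
        assert degs.bh_adjust([]).size == 0

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_never_decreases_and_order_preserving(self, pvals):
        p = np.array(pvals)
        adj = degs.bh_adjust(p)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestNBDifferentialExpression:
    def test_duplicated_groups_give_zero_degs(self, default_counts):
        _, counts, design, _ = default_counts
        ctrl = counts[["control_1", "control_2", "control_3"]]
        dup = pd.concat([ctrl, ctrl.set_axis(["x_1", "x_2", "x_3"], axis=1)],
                        axis=1)
        dsg = pd.DataFrame({
            "condition": ["control"] * 3 + ["x"] * 3,
            "replicate": [1, 2, 3] * 2,
        }, index=dup.columns)
        table = rk.call_degs(dup, dsg, ("x", "control"))
        tested = table.dropna(subset=["log2fc"])
        np.testing.assert_allclose(tested.log2fc, 0.0, atol=1e-12)
        assert table.is_deg.sum() == 0

    def test_planted_genes_detected_with_direction(self, default_counts):
        _, counts, design, truth = default_counts
        table = rk.call_degs(counts, design, ("drug", "control"))
        planted = truth["class"] != "null"
        detected = table.loc[planted, "is_deg"]
        assert detected.mean() >= 0.9
        hits = table.loc[planted & table.is_deg]
        expect = truth.loc[hits.index, "class"].map(
            {"drug_up": "up", "drug_down": "down"})
        assert (hits.direction == expect).all()

    def test_null_simulation_controls_fdr(self):
        any_false = []
        for seed in range(10):
            counts, design, _ = rk.gen_counts(rk.CountsSimSpec(
                n_genes=1000, n_drug_down=0, n_drug_up=0, seed=500 + seed))
            table = rk.call_degs(counts, design, ("drug", "control"))
            any_false.append(table.is_deg.sum() > 0)
        assert np.mean(any_false) <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 10)

    def test_low_count_genes_filtered(self, default_counts):
        _, counts, design, _ = default_counts
        counts = counts.copy()
        counts.iloc[0] = 0
        counts.iloc[1] = [1, 0, 0, 0, 0, 0] * 3
        model = degs.NBDifferentialExpression().fit(counts, design, ("drug", "control"))
        assert model.n_filtered_ >= 2
        assert np.isnan(model.results_.iloc[0].pvalue)
        assert not model.results_.iloc[0].is_deg

    def test_missing_replicates_rejected(self, default_counts):
        _, counts, design, _ = default_counts
        solo = design[design.index.isin(["control_1", "drug_1", "drug_2"])]
        with pytest.raises(InsufficientDataError):
            rk.call_degs(counts[solo.index], solo, ("drug", "control"))


class TestCoreGeneSet:
    def _table(self, flags: dict):
        genes = list(flags)
        return pd.DataFrame({
            "pvalue": 0.01, "is_deg": [flags[g] is not None for g in genes],
            "direction": [flags[g] or "none" for g in genes]}, index=genes)

    def test_set_difference_and_restored_fraction(self):
        drug = self._table({"g1": "up", "g2": "down", "g3": "up", "g4": "down",
                            "g5": None})
        combo = self._table({"g1": None, "g2": "down", "g3": None, "g4": None,
                             "g5": None})
        core = rk.core_gene_set(drug, combo)
        assert set(core.members) == {"g1", "g3", "g4"}
        assert core.restored_fraction_pct == pytest.approx(75.0)
        assert core.n_up == 2 and core.n_down == 1

    def test_full_persistence_gives_empty_core(self):
        drug = self._table({"g1": "up", "g2": "down"})
        core = rk.core_gene_set(drug, drug)
        assert not core.members
        assert core.restored_fraction_pct == 0.0

    def test_mismatched_universes_rejected(self):
        a = self._table({"g1": "up"})
        b = self._table({"g2": "up"})
        with pytest.raises(ParameterError):
            rk.core_gene_set(a, b)

    def test_round_trip_restores_planted_fraction(self, default_counts):
        spec, counts, design, _ = default_counts
        drug = rk.call_degs(counts, design, ("drug", "control"))
        combo = rk.call_degs(counts, design, ("drug_serum", "control"))
        core = rk.core_gene_set(drug, combo)
        assert abs(core.restored_fraction_pct
                   - 100 * spec.rescued_fraction_serum) < 5.0
        # core members are never differential in the combined condition
        assert not combo.loc[list(core.members), "is_deg"].any()


class TestPermutationOverlap:
    def test_full_universe_sets_give_p_one(self):
        u = [f"g{i}" for i in range(12)]
        res = rk.permutation_overlap_test([set(u), set(u)], [u, u],
                                          n_iter=200, seed=0)
        assert res.p_value == 1.0 and res.observed == 12

    def test_matches_exact_hypergeometric_tail(self):
        u = [f"g{i}" for i in range(20)]
        a, b = set(u[:5]), set(u[:5])
        res = rk.permutation_overlap_test([a, b], [u, u], n_iter=10_000, seed=1)
        exact = stats.hypergeom.sf(4, 20, 5, 5)
        se = np.sqrt(exact * (1 - exact) / 10_000)
        assert abs(res.p_value - exact) <= 3 * se + 1e-12

    def test_three_sets_zero_overlap_gives_p_one(self):
        u = [f"g{i}" for i in range(30)]
        sets = [set(u[:5]), set(u[5:10]), set(u[10:15])]
        res = rk.permutation_overlap_test(sets, [u, u, u], n_iter=300, seed=2)
        assert res.observed == 0 and res.p_value == 1.0

    def test_set_exceeding_universe_rejected(self):
        with pytest.raises(ParameterError):
            rk.permutation_overlap_test([{"a", "b"}, {"a"}], [["a"], ["a"]],
                                        n_iter=10, seed=0)

    def test_zero_p_annotated_as_resolution_bound(self):
        u = [f"g{i}" for i in range(40)]
        res = rk.permutation_overlap_test([set(u[:10]), set(u[:10])], [u, u],
                                          n_iter=1000, seed=3)
        if res.p_value == 0.0:
            assert res.p_annotation == "< 0.001"


class TestDEGOverlapSummary:
    def _table(self, genes, deg_dirs):
        return pd.DataFrame({
            "pvalue": 0.5,
            "is_deg": [g in deg_dirs for g in genes],
            "direction": [deg_dirs.get(g, "none") for g in genes]},
            index=genes)

    def test_identical_tables_overlap_fully(self):
        genes = [f"g{i}" for i in range(30)]
        dirs = {"g0": "up", "g1": "up", "g2": "down"}
        t = self._table(genes, dirs)
        summary = rk.deg_overlap_summary(t, t, n_iter=100, seed=0)
        assert (summary.pct_of_a == 100.0).all()

    def test_disjoint_sets_overlap_zero(self):
        genes = [f"g{i}" for i in range(30)]
        a = self._table(genes, {"g0": "up"})
        b = self._table(genes, {"g5": "up"})
        summary = rk.deg_overlap_summary(a, b, n_iter=100, seed=0)
        up = summary.set_index("direction").loc["up"]
        assert up.pct_of_a == 0.0
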