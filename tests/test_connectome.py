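"""Synapse-table filtering, allocation, thresholds and composition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from thermowire.connectome import (
    allocate_partners,
    assign_glomerulus,
    class_composition,
    estimate_report_threshold,
    innervation_symmetry,
)
from thermowire.errors import ClusteringError, InvalidArgumentError
from thermowire.synthetic import GlomerulusSpec, gen_synapse_table


class TestAllocatePartners:
    def test_toy_table_hand_computation(self, toy_synapse_table):
        # A->P1:12, B->P1:2, A->P2:5, B->P2:6, A->P3:4 with defaults:
        # B->P1 dropped (<3), P3 dropped (<10 total); fractions 12/23 and 11/23
        alloc = allocate_partners(toy_synapse_table)
        assert list(alloc.partners["post_id"]) == ["P1", "P2"]
        assert list(alloc.partners["total_synapses"]) == [12, 11]
        np.testing.assert_allclose(alloc.partners["fraction"], [12 / 23, 11 / 23])
        assert list(alloc.partners["rank"]) == [1, 2]
        assert list(alloc.dropped["post_id"]) == ["P3"]

    def test_everything_below_connection_filter(self, toy_synapse_table):
        alloc = allocate_partners(toy_synapse_table, min_per_connection=20)
        assert len(alloc) == 0

    def test_no_filtering_fractions_sum_to_one(self, toy_synapse_table):
        alloc = allocate_partners(toy_synapse_table, min_per_connection=1, min_total=1)
        assert alloc.partners["fraction"].sum() == pytest.approx(1.0, abs=1e-12)
        assert alloc.partners["total_synapses"].sum() == len(toy_synapse_table)

    def test_retained_fractions_normalized(self, toy_synapse_table):
        alloc = allocate_partners(toy_synapse_table)
        assert alloc.partners["fraction"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_prefilter_normalization_flag(self, toy_synapse_table):
        alloc = allocate_partners(toy_synapse_table, normalize_prefilter=True)
        np.testing.assert_allclose(alloc.partners["fraction"], [12 / 29, 11 / 29])

    def test_idempotent_on_retained_output(self, toy_synapse_table):
        alloc = allocate_partners(toy_synapse_table)
        retained_posts = set(alloc.partners["post_id"])
        surviving = toy_synapse_table.merge(
            alloc.partners[["post_id"]], on="post_id")
        kept = surviving.groupby(["pre_id", "post_id"]).size()
        surviving = surviving.set_index(["pre_id", "post_id"]).loc[
            kept[kept >= 3].index].reset_index()
        again = allocate_partners(surviving)
        pd.testing.assert_frame_equal(again.partners, alloc.partners)
        assert set(again.partners["post_id"]) == retained_posts

    def test_raising_min_total_never_retains_more(self, toy_synapse_table):
        sizes = [len(allocate_partners(toy_synapse_table, min_total=m))
                 for m in range(0, 30, 3)]
        assert sizes == sorted(sizes, reverse=True)

    def test_empty_table_gives_empty_allocation(self):
        empty = pd.DataFrame(columns=["pre_id", "pre_type", "post_id", "x", "y", "z"])
        alloc = allocate_partners(empty)
        assert len(alloc) == 0

    def test_rank_tie_break_by_post_id(self):
        spec = GlomerulusSpec("g", "OrX", [("A", "Pb", 12), ("A", "Pa", 12)])
        alloc = allocate_partners(gen_synapse_table([spec], seed=0))
        assert list(alloc.partners["post_id"]) == ["Pa", "Pb"]

    def test_mixed_pre_types_rejected(self, toy_synapse_table):
        bad = toy_synapse_table.copy()
        bad.loc[0, "pre_type"] = "Or7a"
        with pytest.raises(InvalidArgumentError):
            allocate_partners(bad)


class TestReportThreshold:
    def test_hand_example(self):
        assert estimate_report_threshold([50, 30, 12, 9, 4], 3) == 9

    def test_matches_brute_force(self):
        totals = [50, 30, 12, 9, 4]
        for observed in range(0, 7):
            got = estimate_report_threshold(totals, observed)
            brute = next(s for s in range(0, 100)
                         if sum(t > s for t in totals) <= observed)
            assert got == brute

    def test_boundary_cases(self):
        totals = [50, 30, 12, 9, 4]
        assert estimate_report_threshold(totals, 0) == 50  # nothing reported
        assert estimate_report_threshold(totals, len(totals)) == 0
        assert estimate_report_threshold([], 2) == 0

    @settings(derandomize=True, max_examples=30)
    @given(totals=st.lists(st.integers(1, 60), min_size=1, max_size=12),
           o1=st.integers(0, 12), o2=st.integers(0, 12))
    def test_monotone_in_observed_count(self, totals, o1, o2):
        lo, hi = sorted((o1, o2))
        assert estimate_report_threshold(totals, lo) >= estimate_report_threshold(totals, hi)


class TestAssignGlomerulus:
    def test_well_separated_blobs_recovered_exactly(self):
        specs = [GlomerulusSpec(f"g{i}", "Or42b", [("A", f"P{i}", 60)]) for i in range(2)]
        table = gen_synapse_table(specs, coordinate_spread=0.5, separation=40.0, seed=3)
        labeled = assign_glomerulus(table, 2, seed=0)
        crosstab = pd.crosstab(labeled["glomerulus_true"], labeled["glomerulus"])
        assert (crosstab.max(axis=1) == crosstab.sum(axis=1)).all()

    def test_single_cluster_trivial(self, toy_synapse_table):
        labeled = assign_glomerulus(toy_synapse_table, 1)
        assert labeled["glomerulus"].nunique() == 1

    def test_overlapping_blobs_above_chance(self):
        from sklearn.metrics import adjusted_rand_score
        specs = [GlomerulusSpec(f"g{i}", "Or42b", [("A", f"P{i}", 80)]) for i in range(3)]
        table = gen_synapse_table(specs, coordinate_spread=1.0, separation=5.0, seed=4)
        labeled = assign_glomerulus(table, 3, seed=0)
        ari = adjusted_rand_score(labeled["glomerulus_true"], labeled["glomerulus"])
        assert ari > 0.9

    def test_rigid_motion_stability(self):
        specs = [GlomerulusSpec(f"g{i}", "Or42b", [("A", f"P{i}", 50)]) for i in range(2)]
        table = gen_synapse_table(specs, coordinate_spread=0.5, separation=30.0, seed=5)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        moved = table.copy()
        moved[["x", "y", "z"]] = table[["x", "y", "z"]].to_numpy() @ rot.T + 5.0
        a = assign_glomerulus(table, 2, seed=0)["glomerulus"]
        b = assign_glomerulus(moved, 2, seed=0)["glomerulus"]
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(a, b) == pytest.approx(1.0)

    def test_degenerate_coordinates_rejected(self):
        spec = GlomerulusSpec("g", "Or42b", [("A", "P", 30)])
        table = gen_synapse_table([spec], coordinate_spread=0.0, seed=6)
        with pytest.raises(ClusteringError):
            assign_glomerulus(table, 2)


class TestComposition:
    def test_single_class_is_hundred_percent(self, toy_synapse_table):
        alloc = allocate_partners(toy_synapse_table)
        comp = class_composition(alloc, {"P1": "uPN", "P2": "uPN"})
        assert list(comp["post_class"]) == ["uPN"]
        assert comp["percent"].iloc[0] == pytest.approx(100.0)

    def test_planted_composition_recovered(self, toy_synapse_table):
        alloc = allocate_partners(toy_synapse_table)
        comp = class_composition(alloc, {"P1": "uPN", "P2": "mPN"})
        assert dict(zip(comp["post_class"], comp["count"])) == {"uPN": 1, "mPN": 1}
        assert comp["percent"].sum() == pytest.approx(100.0)

    def test_missing_labels_fall_to_other(self, toy_synapse_table):
        alloc = allocate_partners(toy_synapse_table)
        comp = class_composition(alloc, {"P1": "uPN"})
        assert dict(zip(comp["post_class"], comp["count"])) == {"uPN": 1, "other": 1}

    def test_empty_allocation_gives_empty_composition(self):
        empty = pd.DataFrame(columns=["pre_id", "pre_type", "post_id", "x", "y", "z"])
        comp = class_composition(allocate_partners(empty))
        assert comp.empty


class TestInnervationSymmetry:
    def test_balanced_is_zero(self):
        assert innervation_symmetry(120.0, 120.0) == 0.0

    def test_hand_value_and_bounds(self):
        assert innervation_symmetry(300.0, 100.0) == pytest.approx(25.0)
        assert innervation_symmetry(1.0, 0.0) == pytest.approx(50.0)
        assert innervation_symmetry(0.0, 1.0) == pytest.approx(-50.0)

    @settings(derandomize=True, max_examples=40)
    @given(l=st.floats(0, 1e6), r=st.floats(0, 1e6))
    def test_antisymmetric_and_bounded(self, l, r):
        if l + r == 0:
            return
        v = innervation_symmetry(l, r)
        assert v == pytest.approx(-innervation_symmetry(r, l), abs=1e-9)
        assert -50.0 <= v <= 50.0

    def test_both_zero_rejected(self):
        with pytest.raises(InvalidArgumentError):
            innervation_symmetry(0.0, 0.0)
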