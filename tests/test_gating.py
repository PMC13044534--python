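"""Gating: transform, thresholds, floors, QC, positivity calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmequant import gating
from tmequant.gating import (
    CAF_PANEL,
    MACROPHAGE_PANEL,
    DegenerateDistributionError,
    FloorRule,
    GatingError,
    arcsinh_transform,
    build_gates,
    calibrate_floor,
    call_positivity,
    is_unimodal,
    kmeans_threshold,
    mad_fallback_threshold,
    manual_gates,
    mihc_panel,
    qc_filter,
)
from _oracles import best_split_partition


class TestArcsinh:
    def test_known_values(self):
        assert arcsinh_transform(0.0, 150.0) == 0.0
        assert arcsinh_transform(150.0, 150.0) == pytest.approx(
            np.log(1 + np.sqrt(2)), abs=1e-9
        )
        assert float(arcsinh_transform(150.0, 150.0)) == pytest.approx(0.881374, abs=1e-6)

    def test_invalid_cofactor(self):
        with pytest.raises(GatingError):
            arcsinh_transform(1.0, 0.0)

    @given(st.floats(0, 1e6), st.floats(0, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing(self, a, b):
        if a == b:
            return
        lo, hi = sorted([a, b])
        assert arcsinh_transform(lo, 150.0) < arcsinh_transform(hi, 150.0)


class TestKmeansThreshold:
    def test_symmetric_clusters(self):
        v = [0, 0, 0, 10, 10, 10]
        assert kmeans_threshold(v) == 5.0
        assert (np.array(v) > 5.0).sum() == 3

    def test_two_values(self):
        assert kmeans_threshold([1, 2]) == 1.5

    def test_identical_values_degenerate(self):
        with pytest.raises(DegenerateDistributionError):
            kmeans_threshold([3.0, 3.0, 3.0])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_split_on_mixtures(self, seed):
        """The returned threshold induces exactly the partition found by
        scanning all n-1 cut points for the within-class SSE minimum."""
        rng = np.random.default_rng(seed)
        w = rng.uniform(0.1, 0.9)
        n = int(rng.integers(50, 2000))
        n1 = int(w * n)
        sep = rng.uniform(2.5, 8.0)
        v = np.concatenate([
            rng.normal(1.0, 0.2, n1),
            rng.normal(1.0 + sep * 0.35, 0.5, n - n1),
        ])
        thr = kmeans_threshold(v)
        np.testing.assert_array_equal(v > thr, best_split_partition(v))

    def test_spec_mixture_example(self):
        rng = np.random.default_rng(42)
        v = np.concatenate([rng.normal(1, 0.2, 500), rng.normal(5, 0.5, 500)])
        thr = kmeans_threshold(v)
        np.testing.assert_array_equal(v > thr, best_split_partition(v))
        assert 2.0 < thr < 4.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        v = np.concatenate([rng.normal(0, 1, 300), rng.normal(6, 1, 300)])
        t1 = kmeans_threshold(v)
        t2 = kmeans_threshold(rng.permutation(v))
        assert t1 == t2


class TestMadFallback:
    def test_hand_computed(self):
        assert mad_fallback_threshold(range(1, 10)) == 11.0  # med 5, MAD 2

    def test_constant_vector(self):
        assert mad_fallback_threshold([4.0] * 6) == 4.0

    def test_sparse_positive_weakness(self):
        # documented weakness: majority ties give MAD 0
        assert mad_fallback_threshold([0, 0, 0, 0, 100]) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(GatingError):
            mad_fallback_threshold([])


class TestUnimodality:
    def test_gaussian_is_unimodal(self):
        rng = np.random.default_rng(0)
        assert is_unimodal(rng.normal(size=1000))

    def test_wide_mixture_is_bimodal(self):
        rng = np.random.default_rng(1)
        v = np.concatenate([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        assert not is_unimodal(v)

    def test_constant_is_unimodal(self):
        assert is_unimodal([2.0] * 50)

    def test_lognormal_background_is_unimodal(self, control_cells):
        v = arcsinh_transform(control_cells["CD68"].to_numpy(), 150.0)
        assert is_unimodal(v)


class TestFloors:
    def test_fpr_budget_order_statistics(self):
        v = np.arange(1, 1001, dtype=float)
        floor = calibrate_floor(v, FloorRule(kind="fpr_budget",
                                             budgets={"m": 0.05}), "m")
        assert 950.0 <= floor < 951.0
        assert (v > floor).mean() <= 0.05
        assert (v > floor).sum() == 50

    def test_fixed_percentile_type7(self):
        v = np.arange(1, 201, dtype=float)
        floor = calibrate_floor(
            v, FloorRule(kind="fixed_control_percentile", percentile=99.5)
        )
        assert floor == np.quantile(v, 0.995)
        assert floor == pytest.approx(199.0, abs=0.01)

    def test_constant_controls(self):
        floor = calibrate_floor(
            [7.0] * 100, FloorRule(kind="fpr_budget", budgets={"m": 0.05}), "m"
        )
        assert floor == 7.0
        assert (np.array([7.0] * 100) > floor).mean() == 0.0

    def test_missing_budget_rejected(self):
        with pytest.raises(GatingError):
            calibrate_floor([1.0, 2.0],
                            FloorRule(kind="fpr_budget", budgets={"x": 0.05}),
                            "y")


class TestQcFilter:
    def test_boundary_at_500(self):
        cells = pd.concat([
            pd.DataFrame({"image_id": f"i{n}", "v": np.zeros(n)})
            for n in (499, 500, 501)
        ])
        kept, log = qc_filter(cells, 500)
        assert set(kept["image_id"]) == {"i500", "i501"}
        assert list(log["image_id"]) == ["i499"]

    def test_empty_cohort(self):
        kept, log = qc_filter(pd.DataFrame({"image_id": []}), 500)
        assert kept.empty and log.empty

    def test_identity_when_all_pass(self):
        cells = pd.DataFrame({"image_id": ["a"] * 600 + ["b"] * 700})
        kept, log = qc_filter(cells, 500)
        assert len(kept) == 1300 and log.empty


class TestBuildGates:
    def test_kmeans_inside_bounds_untouched(self, primary_image, control_cells):
        cells, _ = primary_image
        gates = build_gates(cells, control_cells, CAF_PANEL, apply_qc=False)
        ck = gates[gates["marker"] == "CK19"].iloc[0]
        assert ck["method"] == "kmeans"
        assert ck["final_threshold"] == pytest.approx(
            min(max(ck["raw_threshold"], ck["floor_value"]), ck["cap_value"])
        )
        # bimodal marker with floor below and cap above: clipping is a no-op
        assert ck["floor_value"] < ck["raw_threshold"] < ck["cap_value"]
        assert ck["final_threshold"] == ck["raw_threshold"]

    def test_background_image_floored_to_budget(self, imaging_cfg, control_cells):
        """Pure-background image: fallback threshold sits below the control
        floor, so the floor wins and the positive fraction respects the
        marker's FPR budget."""
        from tmequant import synthgen

        stained = synthgen.gen_control(imaging_cfg, 5000, image_id="blank")
        gates = build_gates(stained, control_cells, CAF_PANEL, apply_qc=False)
        pos = call_positivity(stained, gates, CAF_PANEL)
        for marker, budget in CAF_PANEL.floor_rule.budgets.items():
            row = gates[gates["marker"] == marker].iloc[0]
            assert row["final_threshold"] >= row["floor_value"] or (
                row["final_threshold"] == row["cap_value"]
            )
            # out-of-sample backgound FPR within ~2x budget (sampling noise)
            assert pos[marker].mean() <= 2.5 * budget

    def test_raw_above_cap_clipped(self):
        rng = np.random.default_rng(0)
        # a rare far-out positive cluster: the k-means split sits above the
        # image's 99th percentile, so the cap wins
        cells = pd.DataFrame({
            "image_id": "i", "cell_id": [f"c{i}" for i in range(1000)],
            "M": np.concatenate([rng.normal(0, 1, 990), rng.normal(100, 1, 10)]),
        })
        panel = gating.PanelSpec(name="p", markers=("M",), cap_percentile=99.0)
        gates = build_gates(cells, None, panel, apply_qc=False)
        row = gates.iloc[0]
        assert row["final_threshold"] == row["cap_value"]

    def test_missing_controls_rejected(self, primary_image):
        cells, _ = primary_image
        with pytest.raises(GatingError):
            build_gates(cells, None, CAF_PANEL, apply_qc=False)


class TestCallPositivity:
    def test_tie_at_threshold_is_negative(self):
        cells = pd.DataFrame({
            "cell_id": ["a", "b"], "image_id": "i", "M": [5.0, 5.1]
        })
        gates = manual_gates({"M": 5.0}, ["i"])
        pos = call_positivity(cells, gates)
        assert list(pos["M"]) == [False, True]

    def test_missing_gate_names_image_and_marker(self):
        cells = pd.DataFrame({
            "cell_id": ["a"], "image_id": "img7", "M": [1.0]
        })
        gates = manual_gates({"M": 5.0}, ["other_image"])
        with pytest.raises(GatingError, match="img7.*'M'"):
            call_positivity(cells, gates)

    def test_planted_fraction_recovered(self, imaging_cfg, control_cells):
        """30%-planted CD68 image recovered within 2 pp through gating."""
        from dataclasses import replace
        from tmequant import synthgen

        profile = synthgen.SiteProfile(
            fractions={"CD68": 0.30, "other": 0.70},
            label_markers={"CD68": ("CD68",), "other": ()},
        )
        cfg = replace(imaging_cfg, site_profiles={"s": profile})
        cells, truth = synthgen.gen_tissue(cfg, "s", n_cells=10_000)
        panel = mihc_panel(["CD68"])
        gates = build_gates(cells, None, panel, apply_qc=False)
        pos = call_positivity(cells, gates, panel)
        assert pos["CD68"].mean() == pytest.approx(0.30, abs=0.02)

    def test_control_fpr_within_budget_in_sample(self, control_cells):
        """In-sample CAF-panel control FPR never exceeds its budget, by
        order-statistic construction of the floors."""
        gates = build_gates(control_cells, control_cells, CAF_PANEL,
                            apply_qc=False)
        pos = call_positivity(control_cells, gates, CAF_PANEL)
        for marker, budget in CAF_PANEL.floor_rule.budgets.items():
            assert pos[marker].mean() <= budget + 1e-12

    def test_macrophage_floor_is_control_99_5th(self, control_cells):
        gates = build_gates(control_cells, control_cells, MACROPHAGE_PANEL,
                            apply_qc=False)
        for marker in MACROPHAGE_PANEL.markers:
            row = gates[gates["marker"] == marker].iloc[0]
            assert row["floor_value"] == np.quantile(
                control_cells[marker], 0.995
            )

    def test_gating_invariant_to_row_order(self, imaging_cfg):
        from tmequant import synthgen

        cells, _ = synthgen.gen_tissue(imaging_cfg, "primary", n_cells=1500)
        panel = mihc_panel(["CD68", "CK19"])
        shuffled = cells.sample(frac=1.0, random_state=0)
        g1 = build_gates(cells, None, panel, apply_qc=False)
        g2 = build_gates(shuffled, None, panel, apply_qc=False)
        pd.testing.assert_frame_equal(g1, g2)
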