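"""Spatial layer: distances vs. brute force, communities vs. exhaustive
modularity maximization, margin geometry."""

import numpy as np
import pandas as pd
import pytest

from tmequant import spatial
from tmequant.spatial import (
    DistanceSummary,
    build_network,
    cluster_targets,
    detect_communities,
    infiltration_summary,
    map_structures,
    min_distance_matrix,
    pool_summaries,
)
from _oracles import (
    brute_nearest_distances,
    max_modularity_partition,
    weighted_modularity,
)


def _cells(coords_by_class):
    rows = []
    for cls, pts in coords_by_class.items():
        for x, y in pts:
            rows.append({"x_um": x, "y_um": y, "lineage": cls})
    return pd.DataFrame(rows)


class TestMinDistances:
    def test_three_four_five(self):
        cells = _cells({"A": [(0, 0)], "B": [(3, 4)]})
        s = min_distance_matrix(cells)
        assert s.minimum.loc["A", "B"] == 5.0
        assert s.median.loc["A", "B"] == 5.0

    def test_hand_computed_two_refs(self):
        cells = _cells({"A": [(0, 0), (10, 0)], "B": [(0, 1)]})
        s = min_distance_matrix(cells)
        d = [1.0, np.sqrt(101.0)]
        assert s.minimum.loc["A", "B"] == 1.0
        assert s.median.loc["A", "B"] == pytest.approx(sum(d) / 2)

    def test_absent_class_missing_not_zero(self):
        cells = _cells({"A": [(0, 0)]})
        s = min_distance_matrix(cells, classes=["A", "B"])
        assert np.isnan(s.median.loc["A", "B"])
        assert np.isnan(s.median.loc["A", "A"])  # single cell: no neighbor

    def test_directionality(self):
        cells = _cells({"A": [(0, 0), (100, 0)], "B": [(1, 0)]})
        s = min_distance_matrix(cells)
        assert s.median.loc["A", "B"] != s.median.loc["B", "A"]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        classes = ["A", "B", "C"]
        cells = pd.DataFrame({
            "x_um": rng.uniform(0, 500, 400),
            "y_um": rng.uniform(0, 500, 400),
            "lineage": rng.choice(classes, 400),
        })
        s = min_distance_matrix(cells)
        for ref in classes:
            rxy = cells.loc[cells["lineage"] == ref, ["x_um", "y_um"]].to_numpy()
            for tgt in classes:
                txy = cells.loc[cells["lineage"] == tgt,
                                ["x_um", "y_um"]].to_numpy()
                d = brute_nearest_distances(rxy, txy, ref == tgt)
                assert s.median.loc[ref, tgt] == np.median(d)
                assert s.minimum.loc[ref, tgt] == d.min()

    def test_diagonal_positive(self, truth_labeled):
        s = min_distance_matrix(truth_labeled)
        assert (np.diag(s.minimum.to_numpy()) > 0).all()


class TestClusterTargets:
    def _summary(self, med):
        return DistanceSummary(median=med, minimum=med.copy())

    def test_identical_columns_merge_first(self):
        med = pd.DataFrame(
            {"A": [0.0, 5.0, 9.0], "B": [5.0, 0.0, 1.0], "C": [5.0, 0.0, 1.0]},
            index=["A", "B", "C"],
        )
        order = cluster_targets(self._summary(med))
        assert abs(order.index("B") - order.index("C")) == 1

    def test_close_pair_adjacent(self):
        med = pd.DataFrame(
            {"A": [0.0, 1.0, 10.0], "B": [1.0, 0.0, 10.0], "C": [10.0, 10.0, 0.0]},
            index=["A", "B", "C"],
        )
        order = cluster_targets(self._summary(med))
        assert abs(order.index("A") - order.index("B")) == 1

    def test_column_order_invariance(self):
        rng = np.random.default_rng(3)
        m = rng.uniform(0, 100, (4, 4))
        classes = list("ABCD")
        med = pd.DataFrame(m, index=classes, columns=classes)
        o1 = cluster_targets(self._summary(med))
        perm = ["C", "A", "D", "B"]
        o2 = cluster_targets(self._summary(med[perm]))
        assert o1 == o2


class TestNetwork:
    def _graph(self):
        comp = pd.DataFrame({
            "class": list("ABCD"), "pct_of_total": [40.0, 30.0, 20.0, 10.0]
        })
        med = pd.DataFrame(
            np.array([
                [0.0, 10.0, 50.0, 60.0],
                [10.0, 0.0, 55.0, 65.0],
                [50.0, 55.0, 0.0, 12.0],
                [60.0, 65.0, 12.0, 0.0],
            ]),
            index=list("ABCD"), columns=list("ABCD"),
        )
        return comp, DistanceSummary(median=med, minimum=med.copy())

    def test_attraction_closed_form(self):
        comp, summary = self._graph()
        g = build_network(comp, summary, min_pct=1.0, lambda_um=50.0)
        i, j = g.nodes.index("A"), g.nodes.index("B")
        assert g.attraction[i, j] == pytest.approx(np.exp(-10.0 / 50.0))
        k = g.nodes.index("C")
        # d = lambda -> e^-1
        assert np.exp(-g.distance[i, k] / g.distance[i, k]) == pytest.approx(
            np.exp(-1.0)
        )

    def test_node_weights_conserved(self):
        comp, summary = self._graph()
        g = build_network(comp, summary, min_pct=1.0)
        assert g.node_pct.sum() == pytest.approx(100.0)

    def test_min_pct_excludes_small_classes(self):
        comp, summary = self._graph()
        g = build_network(comp, summary, min_pct=15.0)
        assert g.nodes == ["A", "B", "C"]

    def test_too_few_nodes_rejected(self):
        comp, summary = self._graph()
        with pytest.raises(ValueError):
            build_network(comp, summary, min_pct=45.0)


class TestCommunities:
    def _planted_two_block(self, n_per=4, strong=1.0, weak=0.05):
        n = 2 * n_per
        w = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                same = (i < n_per) == (j < n_per)
                w[i, j] = strong if same else 0.0
        w[0, n_per] = w[n_per, 0] = weak  # one weak bridge
        return w

    def _as_graph(self, w):
        from tmequant.spatial import CommunityGraph

        n = len(w)
        return CommunityGraph(
            nodes=[f"n{i}" for i in range(n)],
            node_pct=np.full(n, 100.0 / n),
            distance=np.zeros_like(w),
            attraction=w,
            lambda_um=1.0,
        )

    def test_two_cliques_split_matches_exhaustive(self):
        w = self._planted_two_block()
        g = detect_communities(self._as_graph(w), seed=123)
        q_best, members_best = max_modularity_partition(w)
        assert g.modularity == pytest.approx(q_best, abs=1e-9)
        # same blocks as the brute-force optimum
        a = np.asarray(g.membership)
        assert (a[:4] == a[0]).all() and (a[4:] == a[4]).all() and a[0] != a[4]

    def test_uniform_complete_graph_single_community(self):
        n = 6
        w = np.ones((n, n)) - np.eye(n)
        g = detect_communities(self._as_graph(w), seed=123)
        q_best, _ = max_modularity_partition(w)
        assert g.modularity == pytest.approx(q_best, abs=1e-9)
        assert len(set(g.membership.tolist())) == 1

    def test_seed_reproducibility(self):
        w = self._planted_two_block(strong=0.8, weak=0.3)
        g1 = detect_communities(self._as_graph(w), seed=123)
        g2 = detect_communities(self._as_graph(w), seed=123)
        assert g1.membership.tolist() == g2.membership.tolist()
        assert g1.modularity == g2.modularity

    def test_modularity_definition_agrees_with_oracle(self):
        w = self._planted_two_block()
        g = detect_communities(self._as_graph(w), seed=123)
        assert g.modularity == pytest.approx(
            weighted_modularity(w, g.membership), abs=1e-9
        )

    def test_modularity_in_range(self, truth_labeled):
        from tmequant.phenotyping import composition_summary

        comp = composition_summary(truth_labeled)
        summary = min_distance_matrix(truth_labeled)
        g = detect_communities(build_network(comp, summary), seed=123)
        assert -0.5 <= g.modularity <= 1.0


def _disk_image(n=4000, field=2000.0, radius=500.0, seed=0):
    """Tumor disk centered in the field, non-tumor cells everywhere."""
    rng = np.random.default_rng(seed)
    n_t = n // 2
    rad = radius * np.sqrt(rng.uniform(size=n_t))
    ang = rng.uniform(0, 2 * np.pi, n_t)
    tumor = pd.DataFrame({
        "x_um": field / 2 + rad * np.cos(ang),
        "y_um": field / 2 + rad * np.sin(ang),
        "lineage": "CK19",
    })
    stroma = pd.DataFrame({
        "x_um": rng.uniform(0, field, n - n_t),
        "y_um": rng.uniform(0, field, n - n_t),
        "lineage": rng.choice(["CD3", "CD68", "aSMA", "other"], n - n_t),
    })
    return pd.concat([tumor, stroma], ignore_index=True)


class TestStructures:
    def test_disk_geometry(self):
        cells = _disk_image()
        probes = pd.DataFrame({
            "x_um": [1000 + 450, 1000 + 550, 1000 + 100, 1000 + 900],
            "y_um": [1000.0] * 4,
            "lineage": ["CD3"] * 4,
        })
        a = map_structures(pd.concat([cells, probes], ignore_index=True),
                           margin_um=100.0)
        got = a.region.iloc[-4:].tolist()
        assert got == ["internal_margin", "external_margin",
                       "intratumoral", "stroma"]

    def test_partition_property(self, truth_labeled):
        a = map_structures(truth_labeled)
        assert a.region.notna().all()
        assert set(a.region.unique()) <= set(spatial.REGIONS)
        assert len(a.region) == len(truth_labeled)

    def test_zero_margin_empties_margins(self):
        cells = _disk_image()
        a = map_structures(cells, margin_um=0.0)
        counts = a.region.value_counts()
        # margin bands vanish up to cells sitting exactly on boundary centers
        assert counts.get("internal_margin", 0) + counts.get(
            "external_margin", 0) == 0

    def test_all_tumor_no_stroma(self):
        rng = np.random.default_rng(1)
        cells = pd.DataFrame({
            "x_um": rng.uniform(0, 500, 2000),
            "y_um": rng.uniform(0, 500, 2000),
            "lineage": "CK19",
        })
        a = map_structures(cells)
        assert (a.region != "stroma").all()
        assert not a.eligible  # mask covers everything: no clear boundary

    def test_no_tumor_cells_rejected(self):
        cells = _cells({"CD3": [(0, 0), (10, 10)]})
        with pytest.raises(ValueError):
            map_structures(cells)

    def test_fractured_mask_keeps_largest_component(self):
        rng = np.random.default_rng(2)
        big = pd.DataFrame({
            "x_um": rng.uniform(0, 600, 3000),
            "y_um": rng.uniform(0, 600, 3000),
            "lineage": "CK19",
        })
        small = pd.DataFrame({
            "x_um": rng.uniform(1800, 1900, 150),
            "y_um": rng.uniform(1800, 1900, 150),
            "lineage": "CK19",
        })
        bg = pd.DataFrame({
            "x_um": rng.uniform(0, 2000, 3000),
            "y_um": rng.uniform(0, 2000, 3000),
            "lineage": "CD3",
        })
        cells = pd.concat([big, small, bg], ignore_index=True)
        a = map_structures(cells)
        # cells of the small fragment are outside the analyzed mask
        frag = a.region[3000:3150]
        assert (frag.isin(["stroma", "external_margin"])).all()


class TestInfiltration:
    def test_planted_stromal_t_cell_gradient(self, truth_labeled):
        a = map_structures(truth_labeled)
        tab = infiltration_summary(a, truth_labeled).set_index("class")
        cd3 = tab.loc["CD3"]
        outer = cd3["stroma"] + cd3["external_margin"]
        inner = cd3["intratumoral"] + cd3["internal_margin"]
        assert outer > inner

    def test_rows_sum_to_100(self, truth_labeled):
        a = map_structures(truth_labeled)
        tab = infiltration_summary(a, truth_labeled)
        sums = tab[list(spatial.REGIONS)].sum(axis=1)
        np.testing.assert_allclose(sums, 100.0, rtol=1e-9)

    def test_ineligible_image_rejected(self):
        rng = np.random.default_rng(1)
        cells = pd.DataFrame({
            "x_um": rng.uniform(0, 500, 2000),
            "y_um": rng.uniform(0, 500, 2000),
            "lineage": "CK19",
        })
        a = map_structures(cells)
        with pytest.raises(ValueError):
            infiltration_summary(a, cells)


class TestPooling:
    def test_median_across_images(self):
        m1 = pd.DataFrame([[np.nan, 10.0], [20.0, np.nan]],
                          index=["A", "B"], columns=["A", "B"])
        m2 = pd.DataFrame([[np.nan, 30.0], [40.0, np.nan]],
                          index=["A", "B"], columns=["A", "B"])
        pooled = pool_summaries([
            DistanceSummary(median=m1, minimum=m1),
            DistanceSummary(median=m2, minimum=m2),
        ])
        assert pooled.median.loc["A", "B"] == 20.0
        assert pooled.median.loc["B", "A"] == 30.0
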