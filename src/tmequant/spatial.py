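"""Spatial organization: nearest-neighbor distances, phenotype networks
with seeded community detection, and tumor-margin structure mapping.

Distances are Euclidean on µm centroid coordinates and directional: for
each reference-class cell the distance to its nearest target-class cell is
computed (self excluded when reference = target), then summarized by the
median and the minimum across reference cells.  Target columns of the
median matrix can be ordered by agglomerative clustering for heatmaps.

The phenotype network has one node per class (weight = percent of cells)
and a complete set of edges whose attraction weight is ``exp(-d / lambda)``
with ``d`` the symmetrized median-of-minimum distance — community detection
on a spin-glass model needs positive affinities, so the distance scale is
inverted with a configurable decay length (default: the cohort median of
all pairwise summaries).  Communities come from the spin-glass algorithm
(25 spins, gamma 1) with a fixed RNG seed, 123 by default.

Tumor structure regions are defined from a rasterized tumor-cell density
mask: cells inside the mask within ``margin_um`` of its boundary are the
internal margin, cells outside within ``margin_um`` the external margin,
and the remainders are intratumoral and stroma.  When the mask fractures
into several connected components only the largest is analyzed.  Images
without a clear tumor-stroma boundary (mask covering <5% or >95% of tissue
bins, or a boundary shorter than 10 bins) are ineligible for infiltration
analysis.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.ndimage import binary_fill_holes
from scipy.ndimage import label as cc_label
from scipy.spatial import cKDTree

__all__ = [
    "DistanceSummary",
    "CommunityGraph",
    "StructureAssignment",
    "min_distance_matrix",
    "pool_summaries",
    "cluster_targets",
    "build_network",
    "detect_communities",
    "map_structures",
    "infiltration_summary",
    "REGIONS",
]

REGIONS = ("intratumoral", "internal_margin", "external_margin", "stroma")


@dataclass
class DistanceSummary:
    """Directional reference x target distance summaries (µm)."""

    median: pd.DataFrame
    minimum: pd.DataFrame

    @property
    def classes(self) -> list[str]:
        return list(self.median.index)


def min_distance_matrix(
    cells: pd.DataFrame,
    classes: list[str] | None = None,
    label_col: str = "lineage",
) -> DistanceSummary:
    """Per-reference-cell nearest-target distances, summarized.

    Entry (ref, target) holds the median (resp. minimum) over reference
    cells of the distance to the nearest target cell; self-distances are
    excluded on the diagonal.  A class with no cells (or a diagonal with a
    single cell) yields a missing entry, never zero.
    """
    if classes is None:
        classes = sorted(cells[label_col].unique())
    coords = {
        c: cells.loc[cells[label_col] == c, ["x_um", "y_um"]].to_numpy(float)
        for c in classes
    }
    trees = {c: cKDTree(xy) if len(xy) else None for c, xy in coords.items()}
    med = pd.DataFrame(np.nan, index=classes, columns=classes, dtype=float)
    mn = pd.DataFrame(np.nan, index=classes, columns=classes, dtype=float)
    for ref in classes:
        xy = coords[ref]
        if len(xy) == 0:
            continue
        for tgt in classes:
            tree = trees[tgt]
            if tree is None:
                continue
            if ref == tgt:
                if len(xy) < 2:
                    continue
                d, _ = tree.query(xy, k=2)
                d = d[:, 1]
            else:
                d, _ = tree.query(xy, k=1)
            med.loc[ref, tgt] = float(np.median(d))
            mn.loc[ref, tgt] = float(np.min(d))
    return DistanceSummary(median=med, minimum=mn)


def pool_summaries(summaries: list[DistanceSummary]) -> DistanceSummary:
    """Cohort pooling: the element-wise median across per-image summaries
    (NaN entries ignored)."""
    if not summaries:
        raise ValueError("no summaries to pool")
    classes = sorted({c for s in summaries for c in s.classes})
    def stack(attr):
        mats = [
            getattr(s, attr).reindex(index=classes, columns=classes)
            for s in summaries
        ]
        arr = np.stack([m.to_numpy(float) for m in mats])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
            pooled = np.nanmedian(arr, axis=0)
        return pd.DataFrame(pooled, index=classes, columns=classes)
    return DistanceSummary(median=stack("median"), minimum=stack("minimum"))


def cluster_targets(summary: DistanceSummary) -> list[str]:
    """Dendrogram leaf order of target columns (complete linkage, Euclidean
    distance between median-distance column vectors).  All-missing columns
    are excluded.  Deterministic and invariant to input column order."""
    m = summary.median
    cols = sorted(c for c in m.columns if not m[c].isna().all())
    if len(cols) < 2:
        raise ValueError("need >= 2 target classes with data")
    mat = m[cols].sort_index().to_numpy(float).T  # one row per target column
    # rows with residual NaN (missing ref class) are compared on shared dims
    if np.isnan(mat).any():
        mat = np.nan_to_num(mat, nan=np.nanmax(mat))
    with warnings.catch_warnings():
        # the column vectors can legitimately form a symmetric square array
        warnings.simplefilter("ignore")
        z = linkage(mat, method="complete", metric="euclidean")
    return [cols[i] for i in leaves_list(z)]


@dataclass
class CommunityGraph:
    """Phenotype-class network: node weights are percent of cells, edge
    attractions decay with intercellular distance."""

    nodes: list[str]
    node_pct: np.ndarray
    distance: np.ndarray  # symmetrized median-of-minimum distances
    attraction: np.ndarray  # exp(-d / lambda)
    lambda_um: float
    membership: np.ndarray | None = None
    modularity: float | None = None
    seed: int | None = None


def build_network(
    composition: pd.DataFrame,
    summary: DistanceSummary,
    min_pct: float = 1.0,
    lambda_um: float | None = None,
) -> CommunityGraph:
    """Complete weighted graph over phenotype classes.

    Nodes are classes whose cohort percent of cells is at least ``min_pct``
    (tiny populations destabilize the spin model); node weight is that
    percent.  Edge attraction is ``exp(-d / lambda)`` with ``d`` the
    symmetrized median-of-minimum distance and ``lambda`` defaulting to the
    cohort median of all pairwise distances.

    ``composition`` is a long table with ``class`` and ``pct_of_total``
    columns (multiple rows per class are averaged over samples).
    """
    pct = composition.groupby("class")["pct_of_total"].mean()
    med = summary.median
    classes = [
        c for c in med.index
        if c in pct.index and pct[c] >= min_pct and not med.loc[c].isna().all()
    ]
    if len(classes) < 2:
        raise ValueError("fewer than 2 classes retained for the network")
    d = med.loc[classes, classes].to_numpy(float)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    if lambda_um is None:
        off = d[~np.eye(len(d), dtype=bool)]
        lambda_um = float(np.nanmedian(off))
        if not np.isfinite(lambda_um) or lambda_um <= 0:
            lambda_um = 1.0
    att = np.exp(-d / lambda_um)
    np.fill_diagonal(att, 0.0)
    return CommunityGraph(
        nodes=classes,
        node_pct=pct[classes].to_numpy(float),
        distance=d,
        attraction=att,
        lambda_um=lambda_um,
    )


def detect_communities(
    graph: CommunityGraph,
    seed: int = 123,
    spins: int = 25,
    gamma: float = 1.0,
    restarts: int = 5,
) -> CommunityGraph:
    """Spin-glass community detection with a fixed seed.

    Runs simulated-annealing spin-glass modularity optimization on the
    attraction-weighted graph.  Annealing can stall in a local optimum on
    small graphs, so the sampler is restarted ``restarts`` times from
    seeds derived deterministically from ``seed`` and the highest-modularity
    partition wins; the result is bit-reproducible for a fixed seed (the
    igraph backend draws from Python's seeded ``random``).  Disconnected
    graphs (possible when edges are pruned externally) are handled per
    connected component.  Returns a new graph with membership and weighted
    modularity filled in.
    """
    n = len(graph.nodes)
    edges, weights = [], []
    for i in range(n):
        for j in range(i + 1, n):
            w = graph.attraction[i, j]
            if w > 0:
                edges.append((i, j))
                weights.append(float(w))
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = weights

    def _one_run(run_seed: int) -> np.ndarray:
        random.seed(run_seed)
        membership = np.empty(n, dtype=int)
        offset = 0
        for comp in g.connected_components():
            sub = g.subgraph(comp)
            if sub.vcount() == 1:
                membership[comp[0]] = offset
                offset += 1
                continue
            part = sub.community_spinglass(
                weights="weight", spins=min(spins, sub.vcount()), gamma=gamma
            )
            for local, global_v in enumerate(comp):
                membership[global_v] = offset + part.membership[local]
            offset += len(part)
        return membership

    best_q, membership = -np.inf, None
    for r in range(max(1, restarts)):
        m = _one_run(seed + r)
        q_r = g.modularity(list(m), weights="weight")
        if q_r > best_q:
            best_q, membership = q_r, m
    q = best_q
    out = CommunityGraph(
        nodes=list(graph.nodes),
        node_pct=graph.node_pct.copy(),
        distance=graph.distance.copy(),
        attraction=graph.attraction.copy(),
        lambda_um=graph.lambda_um,
        membership=membership,
        modularity=float(q),
        seed=seed,
    )
    return out


@dataclass
class StructureAssignment:
    """Per-cell tumor-structure regions for one image."""

    region: pd.Series  # indexed like the input cells
    eligible: bool
    reason: str
    mask_fraction: float  # tumor-mask share of occupied tissue bins
    n_boundary_bins: int


def map_structures(
    cells: pd.DataFrame,
    tumor_class: str = "CK19",
    margin_um: float = 100.0,
    grid_um: float = 50.0,
    density_frac: float = 0.25,
    label_col: str = "lineage",
) -> StructureAssignment:
    """Classify every cell into intratumoral / internal margin / external
    margin / stroma relative to a rasterized tumor mask.

    The mask is the set of ``grid_um`` bins whose tumor-class cell count
    exceeds ``density_frac`` times the mean count of non-empty tumor bins;
    only its largest connected component is kept.  Boundary bins are mask
    bins adjacent (4-neighborhood, image border counts) to non-mask bins.
    Cells are assigned by mask membership of their bin and distance to the
    nearest boundary-bin center.
    """
    tumor = cells[cells[label_col] == tumor_class]
    if len(tumor) == 0:
        raise ValueError(f"no {tumor_class!r} cells in image")

    ix = np.floor(cells["x_um"].to_numpy(float) / grid_um).astype(int)
    iy = np.floor(cells["y_um"].to_numpy(float) / grid_um).astype(int)
    nx, ny = ix.max() + 1, iy.max() + 1
    is_tumor = (cells[label_col] == tumor_class).to_numpy()
    counts = np.zeros((nx, ny), int)
    np.add.at(counts, (ix[is_tumor], iy[is_tumor]), 1)
    occupied = np.zeros((nx, ny), bool)
    occupied[ix, iy] = True

    nonzero = counts[counts > 0]
    mask = counts > density_frac * nonzero.mean()
    comps, n_comps = cc_label(mask)
    if n_comps > 1:  # fractured mask: analyze only the largest piece
        sizes = np.bincount(comps.ravel())[1:]
        mask = comps == (int(np.argmax(sizes)) + 1)
    # pinholes from sampling noise are not real stroma inside the tumor
    mask = binary_fill_holes(mask)

    padded = np.pad(mask, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    boundary = mask & ~interior
    b_idx = np.argwhere(boundary)
    n_boundary = len(b_idx)

    mask_fraction = float((mask & occupied).sum() / occupied.sum())
    eligible = 0.05 <= mask_fraction <= 0.95 and n_boundary >= 10
    reason = (
        "ok" if eligible
        else f"unclear tumor-stroma boundary (mask fraction {mask_fraction:.2f}, "
             f"{n_boundary} boundary bins)"
    )

    in_mask = mask[ix, iy]
    if n_boundary:
        centers = (b_idx + 0.5) * grid_um
        tree = cKDTree(centers)
        d, _ = tree.query(np.column_stack([
            cells["x_um"].to_numpy(float), cells["y_um"].to_numpy(float)
        ]))
    else:
        d = np.full(len(cells), np.inf)
    region = np.where(
        in_mask,
        np.where(d <= margin_um, "internal_margin", "intratumoral"),
        np.where(d <= margin_um, "external_margin", "stroma"),
    )
    return StructureAssignment(
        region=pd.Series(region, index=cells.index, name="region"),
        eligible=bool(eligible),
        reason=reason,
        mask_fraction=mask_fraction,
        n_boundary_bins=int(n_boundary),
    )


def infiltration_summary(
    assignment: StructureAssignment,
    labeled: pd.DataFrame,
    tumor_class: str = "CK19",
    other_label: str = "other",
    label_col: str = "lineage",
) -> pd.DataFrame:
    """Per-region composition of non-tumor phenotyped cells.

    Restricted to cells that are phenotyped (not ``other``) and not the
    tumor class.  Returns one row per class (plus an ``all`` row) with the
    percent of that class's cells falling in each of the four regions; rows
    sum to 100 across regions.  Raises on an ineligible image.
    """
    if not assignment.eligible:
        raise ValueError(f"image ineligible for infiltration: {assignment.reason}")
    keep = (labeled[label_col] != tumor_class) & (labeled[label_col] != other_label)
    sub = labeled[keep]
    reg = assignment.region[keep]
    records = []
    groups = [("all", pd.Series(True, index=sub.index))] + [
        (c, sub[label_col] == c) for c in sorted(sub[label_col].unique())
    ]
    for name, mask in groups:
        n = int(mask.sum())
        row = {"class": name, "n": n}
        for region in REGIONS:
            row[region] = (
                100.0 * int((reg[mask] == region).sum()) / n if n else np.nan
            )
        records.append(row)
    return pd.DataFrame.from_records(records)
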