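"""Exclusive phenotype labels and composition / density / area summaries.

A cell positive for several lineage markers receives the first positive
marker in a configurable precedence order (default CK19 > CD3 > CD19 >
CD68 > αSMA: epithelial identity dominates, immune lineage before stroma);
cells positive for no lineage marker are "other".  Modifier markers (IL6,
T-cell transcription factors) are recorded independently of the lineage
call, and αSMA+ cells are subclassified into myofibroblast-like
(myCAF, IL6−) and inflammatory (iCAF, IL6+) fibroblasts.

Percentages are counts divided by total cells (and, separately, by total
phenotyped = non-"other" cells); densities are counts per tissue area.
Tissue area uses a reproducible occupancy-grid surrogate: the number of
occupied ``bin_um`` squares times the bin area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PhenotypeScheme",
    "DEFAULT_SCHEME",
    "TCELL_SCHEME",
    "assign_lineage",
    "composition_summary",
    "mycaf_icaf_ratio",
    "tissue_area",
    "collagen_area_fraction",
    "tf_profile",
]


@dataclass(frozen=True)
class PhenotypeScheme:
    """Rules mapping positivity booleans to one exclusive lineage label."""

    precedence: tuple[str, ...] = ("CK19", "CD3", "CD19", "CD68", "aSMA")
    #: combination classes tested before single-marker precedence,
    #: e.g. CD4+CD8+ double-positive T cells
    combinations: tuple[tuple[str, tuple[str, ...]], ...] = ()
    modifiers: tuple[str, ...] = ("IL6",)
    other_label: str = "other"

    def __post_init__(self):
        if len(set(self.precedence)) != len(self.precedence):
            raise ValueError("precedence list has duplicate markers")

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(
            [name for name, _ in self.combinations]
            + list(self.precedence)
            + [self.other_label]
        )


DEFAULT_SCHEME = PhenotypeScheme()

TCELL_SCHEME = PhenotypeScheme(
    precedence=("CK19", "CD4", "CD8"),
    combinations=(("CD4CD8", ("CD4", "CD8")),),
    modifiers=("Tbet", "FoxP3", "RORgt"),
)


def assign_lineage(
    positivity: pd.DataFrame, scheme: PhenotypeScheme = DEFAULT_SCHEME
) -> pd.DataFrame:
    """Attach an exclusive ``lineage`` label to a positivity table.

    Combination classes win over single markers; otherwise the first
    positive marker in precedence order wins.  Modifier positivity is kept
    as-is (a CD3+IL6+ cell stays labeled CD3 with IL6 True), and a
    ``caf_class`` column marks myCAF/iCAF when the scheme carries αSMA and
    IL6.
    """
    for m in scheme.precedence:
        if m not in positivity.columns:
            raise KeyError(f"positivity table lacks marker {m!r}")
    labeled = positivity.copy()
    lineage = pd.Series(scheme.other_label, index=positivity.index, dtype=object)
    assigned = pd.Series(False, index=positivity.index)
    for name, required in scheme.combinations:
        mask = ~assigned
        for m in required:
            mask &= positivity[m]
        lineage[mask] = name
        assigned |= mask
    for m in scheme.precedence:
        mask = positivity[m] & ~assigned
        lineage[mask] = m
        assigned |= mask
    labeled["lineage"] = lineage

    if "aSMA" in scheme.precedence and "IL6" in positivity.columns:
        caf = pd.Series(pd.NA, index=positivity.index, dtype=object)
        caf[(lineage == "aSMA") & ~positivity["IL6"]] = "myCAF"
        caf[(lineage == "aSMA") & positivity["IL6"]] = "iCAF"
        labeled["caf_class"] = caf
    return labeled


def composition_summary(
    labeled: pd.DataFrame,
    area_mm2: float | Mapping[str, float] | None = None,
    scheme: PhenotypeScheme = DEFAULT_SCHEME,
    by: str = "sample_id",
) -> pd.DataFrame:
    """Per-sample class counts, percentages and densities.

    Returns a long table with one row per (group, class): count,
    pct_of_total (of all cells), pct_of_phenotyped (of non-"other" cells;
    NaN when nothing is phenotyped) and density in cells/mm² when an area
    is supplied (a scalar, or a mapping keyed by group).  area <= 0 raises.
    """
    classes = list(scheme.classes)
    records = []
    for group, sub in labeled.groupby(by, sort=True):
        total = len(sub)
        counts = sub["lineage"].value_counts().reindex(classes, fill_value=0)
        phenotyped = total - int(counts[scheme.other_label])
        if area_mm2 is None:
            area = None
        else:
            area = float(area_mm2[group]) if isinstance(area_mm2, Mapping) else float(area_mm2)
            if area <= 0:
                raise ValueError(f"tissue area for {group!r} must be > 0")
        for cls in classes:
            c = int(counts[cls])
            records.append({
                by: group,
                "class": cls,
                "count": c,
                "pct_of_total": 100.0 * c / total if total else np.nan,
                "pct_of_phenotyped": (
                    np.nan
                    if cls == scheme.other_label or phenotyped == 0
                    else 100.0 * c / phenotyped
                ),
                "density_per_mm2": (c / area) if area else np.nan,
            })
    return pd.DataFrame.from_records(records)


def mycaf_icaf_ratio(
    labeled: pd.DataFrame, by: str = "sample_id"
) -> pd.Series:
    """Per-sample myCAF:iCAF count ratio; NaN when a sample has no iCAF."""
    if "caf_class" not in labeled.columns:
        raise KeyError("labeled table lacks a caf_class column")
    out = {}
    for group, sub in labeled.groupby(by, sort=True):
        n_my = int((sub["caf_class"] == "myCAF").sum())
        n_i = int((sub["caf_class"] == "iCAF").sum())
        out[group] = (n_my / n_i) if n_i else np.nan
    return pd.Series(out, name="mycaf_icaf_ratio")


def tissue_area(cells: pd.DataFrame, bin_um: float = 50.0) -> float:
    """Occupancy-grid tissue area in mm²: the number of ``bin_um`` squares
    containing at least one cell, times the bin area.  Deterministic and
    monotone under adding cells."""
    if len(cells) == 0:
        raise ValueError("empty cell table")
    if bin_um <= 0:
        raise ValueError("bin_um must be > 0")
    ix = np.floor(cells["x_um"].to_numpy() / bin_um).astype(np.int64)
    iy = np.floor(cells["y_um"].to_numpy() / bin_um).astype(np.int64)
    n_bins = len({(a, b) for a, b in zip(ix, iy)})
    return n_bins * (bin_um / 1000.0) ** 2


def collagen_area_fraction(
    image: np.ndarray,
    signal_threshold: float,
    tissue_threshold: float,
) -> float:
    """Percent of tissue pixels carrying collagen signal.

    Tissue = pixels strictly above ``tissue_threshold``; positive = tissue
    pixels strictly above ``signal_threshold``.  Thresholds are fixed once
    per cohort and applied uniformly.  Raises on an empty tissue mask.
    """
    img = np.asarray(image, float)
    tissue = img > tissue_threshold
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise ValueError("no tissue pixels above the tissue threshold")
    n_pos = int((img[tissue] > signal_threshold).sum())
    return 100.0 * n_pos / n_tissue


def tf_profile(
    labeled: pd.DataFrame,
    tfs: Sequence[str] = ("Tbet", "FoxP3", "RORgt"),
    subsets: Sequence[str] = ("CD4", "CD8", "CD4CD8"),
    min_count: int = 25,
    by: str = "sample_id",
) -> pd.DataFrame:
    """Transcription-factor positivity per T-cell subset.

    For each subset: percent of its cells positive for each TF, reported
    per group.  Subsets below ``min_count`` cells are reported missing
    (small parents preclude reliable percentages).
    """
    records = []
    for group, sub in labeled.groupby(by, sort=True):
        for subset in subsets:
            members = sub[sub["lineage"] == subset]
            n = len(members)
            row = {by: group, "subset": subset, "n": n}
            for tf in tfs:
                row[f"{tf}_pct"] = (
                    100.0 * float(members[tf].mean()) if n >= min_count else np.nan
                )
            records.append(row)
    return pd.DataFrame.from_records(records)
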