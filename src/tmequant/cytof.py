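"""Mass-cytometry analysis chain: event cleanup, viability/singlet gating,
sample retention, hierarchical lineage gating and Boolean checkpoint
combination profiling.

Events arrive as per-sample tables (one row per event, one column per
channel) with a bead flag, Gaussian acquisition parameters (residual,
center, offset, width), event length, a cisplatin viability channel and
DNA1/DNA2 intercalator channels.  Cleanup drops bead events and trims each
Gaussian parameter and the event length to a per-sample percentile window
(default 1st-99th).  Live intact singlets are cisplatin-low events inside a
DNA1/DNA2 box.  Samples with at least 500 live DNA2+ cells are retained;
downstream phenotyping of a parent subset additionally requires at least 25
parent events.

Lineage gating is a fixed tree on live singlets: CD45− | CD45+, then CD3+ T
cells split into CD4 / CD8 / CD4+CD8+ double positives, CD3−CD19+ B cells,
remainder "other CD45+".  The five checkpoint channels (CTLA4, LAG3, PD-1,
TIGIT, TIM3 — fixed order) are Boolean-gated into all 32 combinations per
T subset.  Thresholds come from the synthetic generator's known mixture
valleys in tests; a manual threshold table is accepted for real data.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .synthgen import CHECKPOINT_MARKERS

__all__ = [
    "GAUSSIAN_CHANNELS",
    "SUBSETS",
    "DEFAULT_B_RULES",
    "clean_events",
    "live_singlet_gate",
    "count_live",
    "retain_samples",
    "classify_lineage",
    "hierarchical_gate",
    "min_parent_filter",
    "checkpoint_combinations",
    "CheckpointCombos",
    "b_cell_subsets",
]

GAUSSIAN_CHANNELS = ("residual", "center", "offset", "width", "event_length")
SUBSETS = ("CD45neg", "CD45other", "CD4", "CD8", "CD4CD8", "CD19")


def clean_events(
    events: pd.DataFrame,
    window: tuple[float, float] = (1.0, 99.0),
) -> pd.DataFrame:
    """Acquisition cleanup: drop bead-flagged events, then keep events whose
    Gaussian parameters and event length all lie inside their per-sample
    percentile windows (inclusive bounds)."""
    for ch in GAUSSIAN_CHANNELS:
        if ch not in events.columns:
            raise KeyError(f"events lack Gaussian channel {ch!r}")
    lo, hi = window
    if not 0.0 <= lo < hi <= 100.0:
        raise ValueError("percentile window must satisfy 0 <= lo < hi <= 100")
    ev = events[events.get("bead", 0) == 0]
    keep = pd.Series(True, index=ev.index)
    for _, idx in ev.groupby("sample_id").indices.items():
        sub = ev.iloc[idx]
        ok = np.ones(len(sub), bool)
        for ch in GAUSSIAN_CHANNELS:
            v = sub[ch].to_numpy(float)
            a, b = np.quantile(v, [lo / 100.0, hi / 100.0])
            ok &= (v >= a) & (v <= b)
        keep.iloc[idx] = ok
    return ev[keep].copy()


def live_singlet_gate(
    events: pd.DataFrame,
    cisplatin_cut: float,
    dna_box: tuple[tuple[float, float], tuple[float, float]],
) -> pd.DataFrame:
    """Retain live (cisplatin <= cut) intact singlet nucleated events with
    (DNA1, DNA2) inside the box (inclusive bounds)."""
    (d1_lo, d1_hi), (d2_lo, d2_hi) = dna_box
    if d1_lo >= d1_hi or d2_lo >= d2_hi:
        raise ValueError("empty DNA box")
    keep = (
        (events["cisplatin"].to_numpy(float) <= cisplatin_cut)
        & events["DNA1"].between(d1_lo, d1_hi).to_numpy()
        & events["DNA2"].between(d2_lo, d2_hi).to_numpy()
    )
    return events[keep].copy()


def count_live(live_events: pd.DataFrame) -> pd.Series:
    """Live DNA2+ event count per sample (events already live-singlet
    gated, so every event counts)."""
    return live_events.groupby("sample_id").size()


def retain_samples(
    live_counts: pd.Series, min_live: int = 500
) -> tuple[list[str], pd.DataFrame]:
    """Samples with at least ``min_live`` live DNA2+ cells are retained
    (boundary inclusive).  Returns (retained ids, exclusion log)."""
    retained = sorted(live_counts.index[live_counts >= min_live])
    excl = live_counts[live_counts < min_live]
    log = pd.DataFrame({
        "sample_id": excl.index,
        "n_live": excl.to_numpy(),
        "reason": f"fewer than {min_live} live DNA2+ cells",
    }).reset_index(drop=True)
    return retained, log


def classify_lineage(
    events: pd.DataFrame, thresholds: Mapping[str, float]
) -> pd.Series:
    """One exclusive subset label per live singlet event.

    Tree: CD45− dominates any lineage signal; CD45+CD3+ splits by CD4/CD8
    (double positives kept as their own leaf); CD45+CD3−CD19+ is B; the
    remainder is other CD45+.
    """
    for m in ("CD45", "CD3", "CD4", "CD8", "CD19"):
        if m not in thresholds:
            raise KeyError(f"no threshold for marker {m!r}")
        if m not in events.columns:
            raise KeyError(f"events lack marker channel {m!r}")
    pos = {m: events[m].to_numpy(float) > thresholds[m]
           for m in ("CD45", "CD3", "CD4", "CD8", "CD19")}
    label = np.full(len(events), "CD45other", object)
    label[~pos["CD45"]] = "CD45neg"
    t = pos["CD45"] & pos["CD3"]
    label[t & pos["CD4"] & ~pos["CD8"]] = "CD4"
    label[t & pos["CD8"] & ~pos["CD4"]] = "CD8"
    label[t & pos["CD4"] & pos["CD8"]] = "CD4CD8"
    label[pos["CD45"] & ~pos["CD3"] & pos["CD19"]] = "CD19"
    return pd.Series(label, index=events.index, name="subset")


def hierarchical_gate(
    events: pd.DataFrame, thresholds: Mapping[str, float]
) -> pd.DataFrame:
    """Per-sample subset counts/percentages with Ki67+ fractions.

    Input should be live singlets.  The subset partition is exhaustive and
    exclusive: counts sum to the per-sample total.
    """
    subset = classify_lineage(events, thresholds)
    ki67 = (
        events["Ki67"].to_numpy(float) > thresholds["Ki67"]
        if "Ki67" in events.columns and "Ki67" in thresholds
        else None
    )
    records = []
    for sample, idx in events.groupby("sample_id").indices.items():
        lab = subset.iloc[idx]
        total = len(lab)
        for s in SUBSETS:
            mask = (lab == s).to_numpy()
            c = int(mask.sum())
            records.append({
                "sample_id": sample,
                "subset": s,
                "count": c,
                "pct_of_live": 100.0 * c / total if total else np.nan,
                "ki67_pct": (
                    100.0 * float(ki67[idx][mask].mean())
                    if ki67 is not None and c else np.nan
                ),
            })
    return pd.DataFrame.from_records(records)


def min_parent_filter(
    counts: pd.DataFrame, parent: str | Sequence[str], min_events: int = 25
) -> list[str]:
    """Samples whose parent population has at least ``min_events`` events
    (boundary inclusive).  ``parent`` may be one subset or several whose
    counts are summed (e.g. ("CD4", "CD8", "CD4CD8") for CD3+ T cells)."""
    parents = [parent] if isinstance(parent, str) else list(parent)
    known = set(counts["subset"].unique())
    for p in parents:
        if p not in known:
            raise KeyError(f"unknown parent subset {p!r}")
    sub = counts[counts["subset"].isin(parents)]
    totals = sub.groupby("sample_id")["count"].sum()
    return sorted(totals.index[totals >= min_events])


@dataclass
class CheckpointCombos:
    """32-way Boolean checkpoint combination profile for one cell subset."""

    frequencies: pd.DataFrame  # one row per combo, marker state columns + freq
    histogram: pd.Series  # frequency by number of checkpoints per cell (0-5)
    sunburst: pd.DataFrame  # fixed-order hierarchical path table
    n_cells: int
    markers: tuple[str, ...] = CHECKPOINT_MARKERS


def checkpoint_combinations(
    events: pd.DataFrame,
    thresholds: Mapping[str, float],
    markers: Sequence[str] = CHECKPOINT_MARKERS,
) -> CheckpointCombos:
    """Boolean gating of the checkpoint markers into all 2^5 combinations.

    ``events`` should already be restricted to one eligible T subset.
    Frequencies over the 32 states sum to 1; the per-cell checkpoint-count
    histogram aggregates combos by their size.  The sunburst table lists
    marker states in the fixed order with one row per combination.
    """
    markers = tuple(markers)
    pos = np.column_stack([
        events[m].to_numpy(float) > thresholds[m] for m in markers
    ])
    n = len(events)
    codes = pos @ (1 << np.arange(len(markers) - 1, -1, -1))
    counts = np.bincount(codes, minlength=2 ** len(markers))

    rows = []
    for code, combo in enumerate(product([True, False], repeat=len(markers))):
        # code built with first marker as the high bit
        bits = sum(b << (len(markers) - 1 - i) for i, b in enumerate(combo))
        rows.append({
            **{m: combo[i] for i, m in enumerate(markers)},
            "n_positive": int(sum(combo)),
            "label": "+".join(m for i, m in enumerate(markers) if combo[i]) or "none",
            "frequency": counts[bits] / n if n else np.nan,
            "count": int(counts[bits]),
        })
    freq = pd.DataFrame(rows)
    hist = freq.groupby("n_positive")["frequency"].sum()
    hist = hist.reindex(range(len(markers) + 1), fill_value=0.0)

    sun = freq.sort_values(
        by=list(markers), ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    sun["path"] = [
        "/".join(f"{m}{'+' if row[m] else '-'}" for m in markers)
        for _, row in sun.iterrows()
    ]
    return CheckpointCombos(
        frequencies=freq, histogram=hist, sunburst=sun,
        n_cells=n, markers=markers,
    )


#: Default B-cell subset rules: each rule is (all-positive markers,
#: all-negative markers, any-of-positive markers).  These are conventional
#: definitions — naive = IgD+CD27−, memory = CD27+, regulatory potential =
#: PD-1 and/or PD-L1, extrafollicular = IgD−CD27−, plasmablast-like =
#: CD27+IgD−Ki67+, proliferating = Ki67+ — and are fully configurable.
DEFAULT_B_RULES: dict[str, tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]]] = {
    "naive": (("IgD",), ("CD27",), ()),
    "memory": (("CD27",), (), ()),
    "regulatory": ((), (), ("PD1", "PDL1")),
    "extrafollicular": ((), ("IgD", "CD27"), ()),
    "plasmablast": (("CD27", "Ki67"), ("IgD",), ()),
    "proliferating": (("Ki67",), (), ()),
}


def b_cell_subsets(
    events: pd.DataFrame,
    thresholds: Mapping[str, float],
    rules: Mapping[str, tuple] = DEFAULT_B_RULES,
) -> pd.Series:
    """Fractions of CD19+ B cells in each (possibly overlapping) subset.

    ``events`` should be the CD19+ parent of one eligible sample.  A cell
    satisfying an any-of clause once counts once regardless of how many of
    its markers are positive.
    """
    needed = {m for rule in rules.values() for part in rule for m in part}
    for m in needed:
        if m not in events.columns:
            raise KeyError(f"rule references missing channel {m!r}")
        if m not in thresholds:
            raise KeyError(f"no threshold for channel {m!r}")
    pos = {m: events[m].to_numpy(float) > thresholds[m] for m in needed}
    n = len(events)
    out = {}
    for name, (all_pos, all_neg, any_pos) in rules.items():
        mask = np.ones(n, bool)
        for m in all_pos:
            mask &= pos[m]
        for m in all_neg:
            mask &= ~pos[m]
        if any_pos:
            any_mask = np.zeros(n, bool)
            for m in any_pos:
                any_mask |= pos[m]
            mask &= any_mask
        out[name] = float(mask.mean()) if n else np.nan
    return pd.Series(out, name="fraction_of_CD19")
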