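"""Synthetic tissue and mass-cytometry cohorts with planted ground truth.

Every downstream stage of the pipeline (gating, phenotyping, spatial
analysis, CyTOF Boolean gating) is exercised against cohorts produced here,
so each generated table carries a sidecar truth record: the true phenotype
label of every cell, the true modifier states, the true composition of every
image, and the true QC/subset/checkpoint state of every mass-cytometry
event.

The statistical structure emulates whole-slide single-cell exports from
multiplexed immunofluorescence of pancreatic tumors:

* marker intensities are two-component log-normals (background vs. stained),
  right-skewed like fluorescence, with the positive component well above the
  background 99.9th percentile;
* per-site phenotype composition differs between primary tumors and liver
  metastases (epithelial CK19+ cells, αSMA+ fibroblasts, CD3/CD19/CD68
  immune cells, and unphenotyped "other" cells);
* CK19+ tumor cells concentrate in circular nests, immune cells aggregate
  into communities around random anchors, and T cells are depleted inside
  tumor nests so that margin/infiltration analyses have a planted gradient;
* mass-cytometry events carry bead flags, Gaussian acquisition parameters,
  event length, a viability (cisplatin) channel, DNA intercalator channels
  with planted debris and doublets, lineage channels, and five immune
  checkpoint channels whose co-expression is driven by a latent per-cell
  exhaustion score (Gaussian copula), so joint positivity exceeds
  independence.

Determinism: every generator derives its RNG from ``(config.seed, a stable
hash of the operation and site)``, so identical configs produce
byte-identical outputs across runs and operations can be called in any
order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "ConfigurationError",
    "MarkerModel",
    "SiteProfile",
    "SpatialModel",
    "CollagenModel",
    "CytofModel",
    "GeneratorConfig",
    "GroundTruth",
    "default_imaging_config",
    "default_tcell_config",
    "default_cytof_config",
    "default_cytof_thresholds",
    "gen_tissue",
    "gen_control",
    "gen_collagen_image",
    "gen_cytof",
    "gen_cohort",
    "CHECKPOINT_MARKERS",
    "COLLAGEN_SIGNAL_THRESHOLD",
    "COLLAGEN_TISSUE_THRESHOLD",
]


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


#: Fixed checkpoint marker order used throughout (also the sunburst order).
CHECKPOINT_MARKERS = ("CTLA4", "LAG3", "PD1", "TIGIT", "TIM3")

# Pixel levels for synthetic collagen (Picrosirius-red-like) images.
COLLAGEN_SIGNAL_THRESHOLD = 128.0  # polarized-signal classifier cut
COLLAGEN_TISSUE_THRESHOLD = 30.0  # tissue-vs-slide-background cut


@dataclass(frozen=True)
class MarkerModel:
    """Two-component log-normal intensity model for one marker.

    Locations/scales are in natural-log space of arbitrary fluorescence
    units.  The negative component is the cellular background; the positive
    component is real staining.
    """

    neg_mu: float = 3.0
    neg_sigma: float = 0.4
    pos_mu: float = 6.0
    pos_sigma: float = 0.4

    def validate(self, name: str) -> None:
        if self.neg_mu >= self.pos_mu:
            raise ConfigurationError(
                f"marker {name!r}: negative location {self.neg_mu} must lie "
                f"below positive location {self.pos_mu}"
            )
        if self.neg_sigma <= 0 or self.pos_sigma <= 0:
            raise ConfigurationError(f"marker {name!r}: scales must be > 0")


@dataclass(frozen=True)
class SiteProfile:
    """Planted phenotype composition for one anatomic site.

    ``fractions`` maps exclusive phenotype labels to their expected
    fraction of all cells (must sum to 1).  ``label_markers`` maps each
    label to the markers that are truly stained on cells of that label.
    ``modifiers`` maps a modifier marker (e.g. IL6, or a T-cell
    transcription factor) to per-label conditional positive probabilities;
    labels absent from the inner map have probability 0.
    """

    fractions: Mapping[str, float]
    label_markers: Mapping[str, Sequence[str]]
    modifiers: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def validate(self) -> None:
        total = float(sum(self.fractions.values()))
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"phenotype fractions sum to {total!r}, expected 1"
            )
        for lab, f in self.fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError(f"fraction for {lab!r} outside [0, 1]")
            if lab not in self.label_markers:
                raise ConfigurationError(f"label {lab!r} has no marker set")
        for mk, probs in self.modifiers.items():
            for lab, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(
                        f"P({mk}+|{lab}) = {p} outside [0, 1]"
                    )


@dataclass(frozen=True)
class SpatialModel:
    """Planted spatial layout of one image field (µm, origin top-left,
    y increasing downward, matching whole-slide cell exports)."""

    field_um: tuple[float, float] = (2000.0, 2000.0)
    n_nests: int = 3
    nest_radius_um: float = 300.0
    attraction_radius_um: float = 150.0
    #: fraction of community-forming immune cells placed around anchors
    community_fraction: float = 0.6
    n_anchors: int = 4
    #: labels aggregating into immune communities
    community_labels: tuple[str, ...] = ("CD3", "CD19", "CD68")
    #: labels depleted inside tumor nests (planted infiltration gradient)
    stroma_biased_labels: tuple[str, ...] = ("CD3",)
    #: acceptance probability for a stroma-biased cell landing in a nest
    nest_retention: float = 0.2

    def validate(self) -> None:
        w, h = self.field_um
        if w <= 0 or h <= 0:
            raise ConfigurationError("field dimensions must be > 0")
        if self.nest_radius_um >= min(w, h) / 2.0:
            raise ConfigurationError(
                "nest radius must be smaller than half the field"
            )


@dataclass(frozen=True)
class CollagenModel:
    """Planted collagen-positive area fraction per site."""

    area_fraction: Mapping[str, float]
    shape: tuple[int, int] = (512, 512)

    def validate(self) -> None:
        for site, f in self.area_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError(
                    f"collagen fraction for {site!r} outside [0, 1]"
                )


@dataclass(frozen=True)
class CytofModel:
    """Planted structure of mass-cytometry event tables.

    Subset fractions are of all (non-bead) events.  Checkpoint marginals are
    per (site, T subset); co-expression among the five checkpoints follows a
    Gaussian copula with correlation ``coexpression_rho`` driven by a latent
    per-cell exhaustion score (0 = independent positivity).
    """

    subset_fractions: Mapping[str, Mapping[str, float]]
    checkpoint_marginals: Mapping[str, Mapping[str, Mapping[str, float]]]
    coexpression_rho: float = 0.5
    bead_fraction: float = 0.03
    merged_fraction: float = 0.05
    dead_fraction: float = 0.15
    doublet_fraction: float = 0.08
    debris_fraction: float = 0.05
    #: P(Ki67+ | subset, site)
    ki67: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    #: P(marker+ | CD19 B cell, site) for B-phenotype markers
    b_marker_probs: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def validate(self) -> None:
        for site, fr in self.subset_fractions.items():
            total = float(sum(fr.values()))
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"CyTOF subset fractions for {site!r} sum to {total!r}"
                )
            if any(f < 0 for f in fr.values()):
                raise ConfigurationError("negative subset fraction")
        for frac in (
            self.bead_fraction,
            self.merged_fraction,
            self.dead_fraction,
            self.doublet_fraction,
            self.debris_fraction,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError("event fractions must lie in [0, 1]")
        if not 0.0 <= self.coexpression_rho <= 1.0:
            raise ConfigurationError("coexpression_rho must lie in [0, 1]")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic cohort."""

    site_profiles: Mapping[str, SiteProfile]
    intensity_models: Mapping[str, MarkerModel]
    spatial: SpatialModel = SpatialModel()
    collagen: CollagenModel | None = None
    cytof: CytofModel | None = None
    n_samples_per_site: int = 6
    n_cells_per_image: int = 10_000
    tumor_label: str = "CK19"
    seed: int = 0

    def validate(self) -> None:
        for site, profile in self.site_profiles.items():
            profile.validate()
            for markers in profile.label_markers.values():
                for m in markers:
                    if m not in self.intensity_models:
                        raise ConfigurationError(
                            f"site {site!r}: marker {m!r} has no intensity model"
                        )
            for m in profile.modifiers:
                if m not in self.intensity_models:
                    raise ConfigurationError(
                        f"modifier {m!r} has no intensity model"
                    )
        for name, model in self.intensity_models.items():
            model.validate(name)
        self.spatial.validate()
        if self.collagen is not None:
            self.collagen.validate()
        if self.cytof is not None:
            self.cytof.validate()
        if self.n_cells_per_image < 1:
            raise ConfigurationError("n_cells_per_image must be >= 1")


@dataclass
class GroundTruth:
    """Sidecar truth for one generated table.

    ``cells`` has one row per generated cell/event; ``composition`` is the
    empirical truth-label fraction vector (it equals label frequencies
    exactly, by construction).
    """

    cells: pd.DataFrame
    composition: pd.Series

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)


def _rng(config_seed: int, *key: object) -> np.random.Generator:
    """Deterministic per-operation RNG: config seed + CRC32 of a key string."""
    tag = zlib.crc32(":".join(str(k) for k in key).encode()) & 0x7FFFFFFF
    return np.random.default_rng([int(config_seed) & 0x7FFFFFFF, tag])


# ---------------------------------------------------------------------------
# default configurations
# ---------------------------------------------------------------------------

_MAIN_LABEL_MARKERS = {
    "CK19": ("CK19",),
    "aSMA": ("aSMA",),
    "CD3": ("CD3",),
    "CD19": ("CD19",),
    "CD68": ("CD68",),
    "other": (),
}

# Cohort-mean composition planted for the main imaging panel.  αSMA and CD68
# fractions follow the reported cohort means (25.5%/11.2% and 2.44%/8.29%
# of total nucleated cells for primary vs. metastatic); the remaining labels
# are set to plausible cohort values consistent with scarce T cells in
# metastases and a larger epithelial compartment there.
_MAIN_FRACTIONS = {
    "primary": {
        "CK19": 0.30,
        "aSMA": 0.255,
        "CD3": 0.112,
        "CD19": 0.012,
        "CD68": 0.0244,
        "other": 0.2966,
    },
    "metastatic": {
        "CK19": 0.40,
        "aSMA": 0.112,
        "CD3": 0.059,
        "CD19": 0.030,
        "CD68": 0.0829,
        "other": 0.3161,
    },
}

_MAIN_MODIFIERS = {
    # inflammatory-CAF fraction within αSMA+ cells, plus diffuse IL6
    "primary": {"IL6": {"aSMA": 0.30, "CK19": 0.15, "CD3": 0.10,
                        "CD19": 0.10, "CD68": 0.15, "other": 0.08}},
    "metastatic": {"IL6": {"aSMA": 0.18, "CK19": 0.20, "CD3": 0.10,
                           "CD19": 0.12, "CD68": 0.18, "other": 0.10}},
}

_TCELL_LABEL_MARKERS = {
    "CK19": ("CK19",),
    "CD4": ("CD4",),
    "CD8": ("CD8",),
    "CD4CD8": ("CD4", "CD8"),
    "other": (),
}

# T-cell panel: CD4/CD8 fractions follow the reported cohort means
# (CD4 3.19%/5.04%, CD8 7.99%/0.90% primary vs. metastatic); double
# positives are a small planted population.
_TCELL_FRACTIONS = {
    "primary": {"CK19": 0.30, "CD4": 0.0319, "CD8": 0.0799,
                "CD4CD8": 0.006, "other": 0.5822},
    "metastatic": {"CK19": 0.40, "CD4": 0.0504, "CD8": 0.009,
                   "CD4CD8": 0.003, "other": 0.5376},
}

_TCELL_MODIFIERS = {
    "primary": {
        "Tbet": {"CD4": 0.20, "CD8": 0.45, "CD4CD8": 0.25},
        "FoxP3": {"CD4": 0.35, "CD8": 0.08, "CD4CD8": 0.15},
        "RORgt": {"CD4": 0.30, "CD8": 0.10, "CD4CD8": 0.15},
    },
    "metastatic": {
        "Tbet": {"CD4": 0.35, "CD8": 0.50, "CD4CD8": 0.30},
        "FoxP3": {"CD4": 0.15, "CD8": 0.05, "CD4CD8": 0.10},
        "RORgt": {"CD4": 0.12, "CD8": 0.08, "CD4CD8": 0.10},
    },
}

#: CAF-panel markers carry their own gating rules (arcsinh cofactor 150,
#: 99th-percentile caps, per-marker FPR-budget floors).
CAF_MARKERS = ("CK19", "PDPLN", "PDGFRb", "aSMA")
MACROPHAGE_MARKERS = ("CD68", "CCR2", "CD163")


def _default_models(markers: Sequence[str]) -> dict[str, MarkerModel]:
    return {m: MarkerModel() for m in markers}


def default_imaging_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Main imaging-panel cohort: CK19/αSMA/CD3/CD19/CD68 lineages with an
    IL6 modifier, plus CAF- and macrophage-panel channels so the same cells
    can exercise every gating rule."""
    markers = sorted(
        {"IL6", *CAF_MARKERS, *MACROPHAGE_MARKERS, "CK19", "aSMA", "CD3", "CD19"}
    )
    profiles = {}
    for site in ("primary", "metastatic"):
        label_markers = dict(_MAIN_LABEL_MARKERS)
        # CAF co-expression: αSMA+ cells may co-express PDPLN / PDGFRβ
        modifiers = {
            **_MAIN_MODIFIERS[site],
            "PDPLN": {"aSMA": 0.45 if site == "primary" else 0.30},
            "PDGFRb": {"aSMA": 0.12 if site == "primary" else 0.20},
            "CCR2": {"CD68": 0.35 if site == "metastatic" else 0.20},
            "CD163": {"CD68": 0.40 if site == "primary" else 0.20},
        }
        profiles[site] = SiteProfile(
            fractions=_MAIN_FRACTIONS[site],
            label_markers=label_markers,
            modifiers=modifiers,
        )
    cfg = GeneratorConfig(
        site_profiles=profiles,
        intensity_models=_default_models(markers),
        collagen=CollagenModel(
            area_fraction={"primary": 0.35, "metastatic": 0.15}
        ),
        seed=seed,
    )
    cfg = replace(cfg, **overrides)
    cfg.validate()
    return cfg


def default_tcell_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """T-cell imaging-panel cohort: CK19/CD4/CD8/double-positive lineages
    with transcription-factor modifiers (T-bet, FoxP3, RORγt)."""
    markers = ("CK19", "CD4", "CD8", "Tbet", "FoxP3", "RORgt")
    profiles = {
        site: SiteProfile(
            fractions=_TCELL_FRACTIONS[site],
            label_markers=_TCELL_LABEL_MARKERS,
            modifiers=_TCELL_MODIFIERS[site],
        )
        for site in ("primary", "metastatic")
    }
    cfg = GeneratorConfig(
        site_profiles=profiles,
        intensity_models=_default_models(markers),
        seed=seed,
    )
    cfg = replace(cfg, **overrides)
    cfg.validate()
    return cfg


_CYTOF_SUBSETS = ("CD45neg", "CD45other", "CD4", "CD8", "CD4CD8", "CD19")

_CYTOF_FRACTIONS = {
    # primary tumors average ~36% CD45+ cells; metastases are mostly CD45-
    # with relatively more CD8 T and B cells.
    "primary": {"CD45neg": 0.6377, "CD45other": 0.2823, "CD4": 0.035,
                "CD8": 0.025, "CD4CD8": 0.003, "CD19": 0.017},
    "metastatic": {"CD45neg": 0.6675, "CD45other": 0.2345, "CD4": 0.030,
                   "CD8": 0.030, "CD4CD8": 0.002, "CD19": 0.036},
}

# Checkpoint marginal positivity per (site, T subset).  CD8 CTLA4/TIGIT and
# CD4 TIGIT/TIM3 carry the reported cohort means; the rest are plausible
# values consistent with CTLA4/LAG3/PD-1 dominance on CD4 T cells.
_CYTOF_CHECKPOINTS = {
    "primary": {
        "CD4": {"CTLA4": 0.62, "LAG3": 0.58, "PD1": 0.64,
                "TIGIT": 0.4126, "TIM3": 0.3198},
        "CD8": {"CTLA4": 0.4206, "LAG3": 0.48, "PD1": 0.55,
                "TIGIT": 0.5061, "TIM3": 0.28},
    },
    "metastatic": {
        "CD4": {"CTLA4": 0.65, "LAG3": 0.60, "PD1": 0.66,
                "TIGIT": 0.3838, "TIM3": 0.2854},
        "CD8": {"CTLA4": 0.6007, "LAG3": 0.42, "PD1": 0.58,
                "TIGIT": 0.6284, "TIM3": 0.25},
    },
}

_CYTOF_KI67 = {
    "primary": {"CD4": 0.08, "CD8": 0.10, "CD4CD8": 0.08, "CD19": 0.08,
                "CD45other": 0.05, "CD45neg": 0.03},
    "metastatic": {"CD4": 0.10, "CD8": 0.18, "CD4CD8": 0.10, "CD19": 0.16,
                   "CD45other": 0.05, "CD45neg": 0.03},
}

_CYTOF_B_MARKERS = {
    "primary": {"CD27": 0.12, "IgD": 0.60, "PD1": 0.20, "PDL1": 0.15},
    "metastatic": {"CD27": 0.10, "IgD": 0.45, "PD1": 0.35, "PDL1": 0.30},
}

#: lineage channel truth per CyTOF subset
_CYTOF_SUBSET_MARKERS = {
    "CD45neg": (),
    "CD45other": ("CD45", "CD11b"),
    "CD4": ("CD45", "CD3", "CD4"),
    "CD8": ("CD45", "CD3", "CD8"),
    "CD4CD8": ("CD45", "CD3", "CD4", "CD8"),
    "CD19": ("CD45", "CD19"),
}

_CYTOF_CHANNEL_MODEL = MarkerModel(neg_mu=1.5, neg_sigma=0.35,
                                   pos_mu=4.5, pos_sigma=0.35)

# log-space locations of the viability / DNA mixtures
_CISPLATIN_LIVE = (2.5, 0.4)
_CISPLATIN_DEAD = (5.5, 0.3)
_DNA_SINGLET = (5.0, 0.12)
_DNA_DEBRIS = (2.0, 0.5)


def default_cytof_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Mass-cytometry cohort with planted QC classes, lineage subsets and
    copula-correlated checkpoint co-expression."""
    cytof = CytofModel(
        subset_fractions=_CYTOF_FRACTIONS,
        checkpoint_marginals=_CYTOF_CHECKPOINTS,
        ki67=_CYTOF_KI67,
        b_marker_probs=_CYTOF_B_MARKERS,
    )
    # imaging fields are irrelevant for events but the config shell is shared
    cfg = default_imaging_config(seed=seed)
    cfg = replace(cfg, cytof=cytof, **overrides)
    cfg.validate()
    return cfg


def default_cytof_thresholds() -> dict[str, float]:
    """Valley-midpoint positivity cuts for synthetic CyTOF channels (raw
    intensity units): the geometric mean of the two component medians."""
    m = _CYTOF_CHANNEL_MODEL
    cut = float(np.exp((m.neg_mu + m.pos_mu) / 2.0))
    channels = {"CD45", "CD3", "CD4", "CD8", "CD19", "CD11b", "Ki67",
                "CD27", "IgD", "PDL1", *CHECKPOINT_MARKERS}
    return {c: cut for c in sorted(channels)}


def default_live_singlet_gates() -> tuple[float, tuple[tuple[float, float], tuple[float, float]]]:
    """(cisplatin cut, DNA1/DNA2 box) at the planted mixture valleys."""
    cis_cut = float(np.exp((_CISPLATIN_LIVE[0] + _CISPLATIN_DEAD[0]) / 2.0))
    lo = float(np.exp((_DNA_DEBRIS[0] + _DNA_SINGLET[0]) / 2.0))
    hi = float(np.exp((_DNA_SINGLET[0] + _DNA_SINGLET[0] + np.log(2.0)) / 2.0))
    return cis_cut, ((lo, hi), (lo, hi))


# ---------------------------------------------------------------------------
# tissue generation
# ---------------------------------------------------------------------------

def _draw_intensities(
    rng: np.random.Generator,
    models: Mapping[str, MarkerModel],
    positive: Mapping[str, np.ndarray],
    n: int,
) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for marker, model in models.items():
        pos = positive.get(marker)
        neg_draw = rng.lognormal(model.neg_mu, model.neg_sigma, size=n)
        if pos is None or not pos.any():
            out[marker] = neg_draw
            continue
        pos_draw = rng.lognormal(model.pos_mu, model.pos_sigma, size=n)
        out[marker] = np.where(pos, pos_draw, neg_draw)
    return out


def _place_cells(
    rng: np.random.Generator,
    labels: np.ndarray,
    spatial: SpatialModel,
    tumor_label: str,
) -> tuple[np.ndarray, np.ndarray]:
    w, h = spatial.field_um
    n = labels.size
    x = rng.uniform(0.0, w, size=n)
    y = rng.uniform(0.0, h, size=n)

    r = spatial.nest_radius_um
    nests = np.column_stack([
        rng.uniform(r, w - r, size=spatial.n_nests),
        rng.uniform(r, h - r, size=spatial.n_nests),
    ]) if spatial.n_nests > 0 else np.empty((0, 2))

    # tumor cells: uniform in a randomly chosen nest disk
    tumor = labels == tumor_label
    if tumor.any() and len(nests):
        k = tumor.sum()
        which = rng.integers(0, len(nests), size=k)
        rad = r * np.sqrt(rng.uniform(size=k))
        ang = rng.uniform(0.0, 2.0 * np.pi, size=k)
        x[tumor] = np.clip(nests[which, 0] + rad * np.cos(ang), 0.0, w)
        y[tumor] = np.clip(nests[which, 1] + rad * np.sin(ang), 0.0, h)

    # immune communities: attraction around shared anchors
    comm = np.isin(labels, spatial.community_labels)
    if comm.any() and spatial.n_anchors > 0:
        k = comm.sum()
        anchors = np.column_stack([
            rng.uniform(0.0, w, size=spatial.n_anchors),
            rng.uniform(0.0, h, size=spatial.n_anchors),
        ])
        attracted = rng.uniform(size=k) < spatial.community_fraction
        which = rng.integers(0, spatial.n_anchors, size=k)
        sigma = spatial.attraction_radius_um / 2.0
        cx = np.clip(anchors[which, 0] + rng.normal(0.0, sigma, size=k), 0.0, w)
        cy = np.clip(anchors[which, 1] + rng.normal(0.0, sigma, size=k), 0.0, h)
        idx = np.flatnonzero(comm)
        x[idx[attracted]] = cx[attracted]
        y[idx[attracted]] = cy[attracted]

    # stroma-biased labels: thin inside tumor nests (planted gradient)
    if len(nests):
        biased = np.isin(labels, spatial.stroma_biased_labels)
        idx = np.flatnonzero(biased)
        for i in idx:
            for _ in range(20):
                d2 = (nests[:, 0] - x[i]) ** 2 + (nests[:, 1] - y[i]) ** 2
                inside = bool((d2 < r * r).any())
                if not inside or rng.uniform() < spatial.nest_retention:
                    break
                x[i] = rng.uniform(0.0, w)
                y[i] = rng.uniform(0.0, h)
    return x, y


def gen_tissue(
    config: GeneratorConfig,
    site: str,
    image_id: str | None = None,
    sample_id: str | None = None,
    n_cells: int | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one synthetic image's cell table with planted truth.

    Returns a cell table (cell_id, image_id, sample_id, site, x_um, y_um,
    one column per marker) and its :class:`GroundTruth`.
    """
    config.validate()
    if site not in config.site_profiles:
        raise ConfigurationError(f"unknown site {site!r}")
    profile = config.site_profiles[site]
    n = int(n_cells if n_cells is not None else config.n_cells_per_image)
    image_id = image_id or f"{site}_img"
    sample_id = sample_id or image_id
    rng = _rng(config.seed, "tissue", site, image_id)

    labels_order = list(profile.fractions)
    probs = np.array([profile.fractions[l] for l in labels_order], float)
    labels = np.asarray(labels_order, object)[
        rng.choice(len(labels_order), size=n, p=probs / probs.sum())
    ]

    # truth marker states: lineage markers plus stochastic modifiers
    positive: dict[str, np.ndarray] = {}
    for lab in labels_order:
        mask = labels == lab
        for m in profile.label_markers[lab]:
            positive.setdefault(m, np.zeros(n, bool))
            positive[m] |= mask
    modifier_state: dict[str, np.ndarray] = {}
    for mk, probs_by_label in profile.modifiers.items():
        state = np.zeros(n, bool)
        for lab, p in probs_by_label.items():
            mask = labels == lab
            if p > 0 and mask.any():
                state[mask] = rng.uniform(size=int(mask.sum())) < p
        modifier_state[mk] = state
        positive[mk] = positive.get(mk, np.zeros(n, bool)) | state

    x, y = _place_cells(rng, labels, config.spatial, config.tumor_label)
    intensities = _draw_intensities(rng, config.intensity_models, positive, n)

    cell_id = np.array([f"{image_id}_c{i}" for i in range(n)], object)
    cells = pd.DataFrame({
        "cell_id": cell_id,
        "image_id": image_id,
        "sample_id": sample_id,
        "site": site,
        "x_um": x,
        "y_um": y,
        **{m: intensities[m] for m in sorted(intensities)},
    })
    truth_cells = pd.DataFrame({
        "cell_id": cell_id,
        "image_id": image_id,
        "true_label": labels,
        **{f"true_{mk}": st for mk, st in sorted(modifier_state.items())},
    })
    composition = (
        pd.Series(labels).value_counts(normalize=True)
        .reindex(labels_order, fill_value=0.0)
    )
    return cells, GroundTruth(cells=truth_cells, composition=composition)


def gen_control(
    config: GeneratorConfig, n_cells: int, image_id: str = "control"
) -> pd.DataFrame:
    """Unstained negative-control image: every marker drawn from its
    background distribution only."""
    if n_cells < 1:
        raise ConfigurationError("n_cells must be >= 1")
    config.validate()
    rng = _rng(config.seed, "control", image_id)
    n = int(n_cells)
    w, h = config.spatial.field_um
    intensities = _draw_intensities(rng, config.intensity_models, {}, n)
    return pd.DataFrame({
        "cell_id": [f"{image_id}_c{i}" for i in range(n)],
        "image_id": image_id,
        "sample_id": image_id,
        "site": "control",
        "x_um": rng.uniform(0.0, w, size=n),
        "y_um": rng.uniform(0.0, h, size=n),
        **{m: intensities[m] for m in sorted(intensities)},
    })


def gen_collagen_image(
    config: GeneratorConfig, site: str, image_id: str = "collagen"
) -> tuple[np.ndarray, float]:
    """Synthetic polarized-light collagen image.

    A circular tissue region sits on a dark slide background; a planted
    fraction of tissue pixels carries bright fiber signal.  Returns the
    uint8 pixel array and the planted fraction.
    """
    config.validate()
    if config.collagen is None or site not in config.collagen.area_fraction:
        raise ConfigurationError(f"no collagen model for site {site!r}")
    frac = float(config.collagen.area_fraction[site])
    if not 0.0 <= frac <= 1.0:
        raise ConfigurationError("collagen fraction outside [0, 1]")
    rng = _rng(config.seed, "collagen", site, image_id)
    ny, nx = config.collagen.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    tissue = (yy - cy) ** 2 + (xx - cx) ** 2 <= (0.45 * min(ny, nx)) ** 2

    img = np.clip(rng.normal(10.0, 3.0, size=(ny, nx)), 0, 255)
    neg = np.clip(rng.normal(60.0, 8.0, size=(ny, nx)), 40, 120)
    pos = np.clip(rng.normal(200.0, 8.0, size=(ny, nx)), 160, 255)
    fiber = rng.uniform(size=(ny, nx)) < frac
    img[tissue] = np.where(fiber[tissue], pos[tissue], neg[tissue])
    return img.astype(np.uint8), frac


# ---------------------------------------------------------------------------
# mass-cytometry generation
# ---------------------------------------------------------------------------

def gen_cytof(
    config: GeneratorConfig,
    site: str,
    sample_id: str | None = None,
    n_events: int = 50_000,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one sample's mass-cytometry event table with planted truth.

    Events carry acquisition QC channels (bead flag, Gaussian residual /
    center / offset / width, event length), viability (cisplatin) and
    DNA1/DNA2 intercalator channels, lineage channels and the five immune
    checkpoint channels.  Checkpoint positivity on T cells follows a
    Gaussian copula on a latent exhaustion score so that co-expression
    exceeds independence when ``coexpression_rho > 0``.
    """
    config.validate()
    if config.cytof is None:
        raise ConfigurationError("config has no cytof model")
    model = config.cytof
    if site not in model.subset_fractions:
        raise ConfigurationError(f"unknown CyTOF site {site!r}")
    sample_id = sample_id or f"{site}_s1"
    rng = _rng(config.seed, "cytof", site, sample_id)
    n = int(n_events)

    is_bead = rng.uniform(size=n) < model.bead_fraction
    is_merged = (~is_bead) & (rng.uniform(size=n) < model.merged_fraction)
    is_dead = (~is_bead) & (rng.uniform(size=n) < model.dead_fraction)
    u = rng.uniform(size=n)
    is_debris = (~is_bead) & (u < model.debris_fraction)
    is_doublet = (~is_bead) & (u >= model.debris_fraction) & (
        u < model.debris_fraction + model.doublet_fraction
    )

    # Gaussian acquisition parameters: N(0,1) for clean events; merged ion
    # clouds deviate by ±8σ with an independent random sign per channel, so
    # two-sided percentile windows on any channel catch them.
    gaussians = {}
    for ch in ("residual", "center", "offset", "width"):
        base = rng.normal(0.0, 1.0, size=n)
        sign = rng.choice([-1.0, 1.0], size=n)
        gaussians[ch] = base + np.where(is_merged, sign * 8.0, 0.0)
    length = rng.normal(30.0, 3.0, size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    length = length + np.where(is_merged, sign * 30.0, 0.0)

    cisplatin = np.where(
        is_dead,
        rng.lognormal(*_CISPLATIN_DEAD, size=n),
        rng.lognormal(*_CISPLATIN_LIVE, size=n),
    )
    dna = rng.lognormal(*_DNA_SINGLET, size=(n, 2))
    dna2x = dna + rng.lognormal(*_DNA_SINGLET, size=(n, 2))
    debris = rng.lognormal(*_DNA_DEBRIS, size=(n, 2))
    dna = np.where(is_doublet[:, None], dna2x, dna)
    dna = np.where(is_debris[:, None], debris, dna)

    fr = model.subset_fractions[site]
    order = [s for s in _CYTOF_SUBSETS if s in fr]
    p = np.array([fr[s] for s in order], float)
    subset = np.asarray(order, object)[
        rng.choice(len(order), size=n, p=p / p.sum())
    ]
    subset[is_bead] = "bead"

    # lineage / functional channel truth states
    channels = sorted(default_cytof_thresholds())
    state = {c: np.zeros(n, bool) for c in channels}
    for sub, marks in _CYTOF_SUBSET_MARKERS.items():
        mask = subset == sub
        for m in marks:
            state[m] |= mask
    ki67 = model.ki67.get(site, {})
    for sub, pk in ki67.items():
        mask = subset == sub
        if pk > 0 and mask.any():
            state["Ki67"][mask] |= rng.uniform(size=int(mask.sum())) < pk
    bprobs = model.b_marker_probs.get(site, {})
    bmask = subset == "CD19"
    for m, pm in bprobs.items():
        if pm > 0 and bmask.any():
            state[m][bmask] |= rng.uniform(size=int(bmask.sum())) < pm

    # checkpoint states on T subsets via a Gaussian copula
    rho = model.coexpression_rho
    z = rng.normal(size=n)
    for sub in ("CD4", "CD8", "CD4CD8"):
        marg_key = "CD4" if sub in ("CD4", "CD4CD8") else "CD8"
        marginals = model.checkpoint_marginals.get(site, {}).get(marg_key)
        if not marginals:
            continue
        mask = subset == sub
        if not mask.any():
            continue
        k = int(mask.sum())
        for m in CHECKPOINT_MARKERS:
            pm = marginals.get(m, 0.0)
            eps = rng.normal(size=k)
            latent = np.sqrt(rho) * z[mask] + np.sqrt(1.0 - rho) * eps
            state[m][mask] = latent <= norm.ppf(pm)

    ch_model = {c: _CYTOF_CHANNEL_MODEL for c in channels}
    intensities = _draw_intensities(rng, ch_model, state, n)

    events = pd.DataFrame({
        "event_id": [f"{sample_id}_e{i}" for i in range(n)],
        "sample_id": sample_id,
        "site": site,
        "bead": is_bead.astype(int),
        **gaussians,
        "event_length": length,
        "cisplatin": cisplatin,
        "DNA1": dna[:, 0],
        "DNA2": dna[:, 1],
        **{c: intensities[c] for c in channels},
    })
    truth = pd.DataFrame({
        "event_id": events["event_id"],
        "sample_id": sample_id,
        "is_bead": is_bead,
        "is_merged": is_merged,
        "is_dead": is_dead,
        "is_doublet": is_doublet,
        "is_debris": is_debris,
        "live_singlet": ~(is_bead | is_merged | is_dead | is_doublet | is_debris),
        "true_subset": subset,
        **{f"true_{m}": state[m] for m in channels},
    })
    composition = (
        pd.Series(subset[~is_bead]).value_counts(normalize=True)
        .reindex(order, fill_value=0.0)
    )
    return events, GroundTruth(cells=truth, composition=composition)


# ---------------------------------------------------------------------------
# cohort convenience
# ---------------------------------------------------------------------------

def gen_cohort(
    config: GeneratorConfig,
    sites: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate ``n_samples_per_site`` images per site (one image per
    sample).  Returns (cells, truth_cells) concatenated across images."""
    config.validate()
    sites = list(sites if sites is not None else config.site_profiles)
    all_cells, all_truth = [], []
    for site in sites:
        for i in range(config.n_samples_per_site):
            sid = f"{site}_s{i + 1}"
            cells, truth = gen_tissue(
                config, site, image_id=sid, sample_id=sid
            )
            all_cells.append(cells)
            all_truth.append(truth.cells)
    return (
        pd.concat(all_cells, ignore_index=True),
        pd.concat(all_truth, ignore_index=True),
    )
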