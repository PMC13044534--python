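"""End-to-end study pipeline on a synthetic cohort.

Glues the stages together in the order a real study runs them: generate
(or load) per-site cell tables and controls, QC-filter, gate, phenotype,
summarize composition, run the spatial layer per site, run the
mass-cytometry chain, compare sites, and assemble the report.  Exists
mainly so the whole chain can be rerun under one seed and checked for
byte-identical output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cytof as cy
from . import gating, phenotyping, spatial, synthgen
from .report import cohort_report
from .stats import mann_whitney

__all__ = ["run_study"]


def run_study(
    config: synthgen.GeneratorConfig,
    cytof_config: synthgen.GeneratorConfig | None = None,
    n_control_cells: int = 5_000,
    n_cytof_events: int = 20_000,
    community_seed: int = 123,
    outdir=None,
) -> dict:
    """Run the full synthetic study once; deterministic given the configs.

    Returns the cohort report dict (tables + manifest).
    """
    sites = list(config.site_profiles)
    cells, truth = synthgen.gen_cohort(config)
    controls = synthgen.gen_control(config, n_control_cells)

    retained, exclusions = gating.qc_filter(cells)
    panel = gating.mihc_panel(
        [m for m in ("CK19", "aSMA", "CD3", "CD19", "CD68", "IL6")
         if m in retained.columns]
    )
    gates = gating.build_gates(retained, controls, panel, apply_qc=False)
    positivity = gating.call_positivity(retained, gates, panel)
    labeled = phenotyping.assign_lineage(positivity)

    areas = {
        sid: phenotyping.tissue_area(sub)
        for sid, sub in retained.groupby("sample_id")
    }
    composition = phenotyping.composition_summary(labeled, area_mm2=areas)

    spatial_tables = []
    community_tables = []
    for site in sites:
        site_labeled = labeled[labeled["site"] == site]
        summaries = [
            spatial.min_distance_matrix(img)
            for _, img in site_labeled.groupby("image_id")
        ]
        pooled = spatial.pool_summaries(summaries)
        long = pooled.median.stack().rename("median_min_dist_um").reset_index()
        long.columns = ["reference", "target", "median_min_dist_um"]
        long["site"] = site
        spatial_tables.append(long)

        site_comp = composition[
            composition["sample_id"].isin(site_labeled["sample_id"].unique())
        ]
        graph = spatial.build_network(site_comp, pooled, min_pct=1.0)
        graph = spatial.detect_communities(graph, seed=community_seed)
        community_tables.append(pd.DataFrame({
            "site": site,
            "node": graph.nodes,
            "pct": graph.node_pct,
            "community": graph.membership,
            "modularity": graph.modularity,
            "seed": community_seed,
        }))

    infiltration = []
    for (site, image_id), img in labeled.groupby(["site", "image_id"]):
        assignment = spatial.map_structures(img)
        if not assignment.eligible:
            continue
        tab = spatial.infiltration_summary(assignment, img)
        tab.insert(0, "image_id", image_id)
        tab.insert(0, "site", site)
        infiltration.append(tab)

    tables = {
        "composition": composition.merge(
            retained[["sample_id", "site"]].drop_duplicates(), on="sample_id"
        ),
        "qc_exclusions": exclusions,
        "distances": pd.concat(spatial_tables, ignore_index=True),
        "communities": pd.concat(community_tables, ignore_index=True),
    }
    if infiltration:
        tables["infiltration"] = pd.concat(infiltration, ignore_index=True)

    if cytof_config is not None and cytof_config.cytof is not None:
        thresholds = synthgen.default_cytof_thresholds()
        cis_cut, dna_box = synthgen.default_live_singlet_gates()
        counts_all = []
        combos_all = []
        for site in cytof_config.site_profiles:
            for i in range(cytof_config.n_samples_per_site):
                sid = f"{site}_cy{i + 1}"
                events, _ = synthgen.gen_cytof(
                    cytof_config, site, sample_id=sid, n_events=n_cytof_events
                )
                clean = cy.clean_events(events)
                live = cy.live_singlet_gate(clean, cis_cut, dna_box)
                kept, _ = cy.retain_samples(cy.count_live(live))
                if sid not in kept:
                    continue
                counts = cy.hierarchical_gate(live, thresholds)
                counts.insert(0, "site", site)
                counts_all.append(counts)
                subset = cy.classify_lineage(live, thresholds)
                for t_subset in ("CD4", "CD8"):
                    ok = cy.min_parent_filter(
                        counts.drop(columns="site"), t_subset
                    )
                    if sid not in ok:
                        continue
                    combos = cy.checkpoint_combinations(
                        live[subset == t_subset], thresholds
                    )
                    f = combos.frequencies.copy()
                    f.insert(0, "subset", t_subset)
                    f.insert(0, "sample_id", sid)
                    f.insert(0, "site", site)
                    combos_all.append(f)
        if counts_all:
            tables["cytof_subsets"] = pd.concat(counts_all, ignore_index=True)
        if combos_all:
            tables["checkpoint_combos"] = pd.concat(combos_all, ignore_index=True)

    # site comparison of per-sample class percentages
    comp = tables["composition"]
    test_rows = []
    if len(sites) == 2:
        for cls, sub in comp.groupby("class"):
            a = sub.loc[sub["site"] == sites[0], "pct_of_total"].to_numpy()
            b = sub.loc[sub["site"] == sites[1], "pct_of_total"].to_numpy()
            if a.size and b.size:
                r = mann_whitney(a, b)
                test_rows.append({
                    "class": cls, "U": r.statistic, "p": r.pvalue,
                    "exact": r.exact,
                })
    if test_rows:
        tables["site_tests"] = pd.DataFrame(test_rows)

    meta = {
        "seed": config.seed,
        "community_seed": community_seed,
        "n_samples_per_site": config.n_samples_per_site,
        "n_cells_per_image": config.n_cells_per_image,
        "sites": sites,
    }
    return cohort_report(tables, meta=meta, outdir=outdir)
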