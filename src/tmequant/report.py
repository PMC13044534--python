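"""Cohort report assembly: per-analysis CSV tables plus a run manifest."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = ["cohort_report", "manifest_hash"]


def manifest_hash(tables: Mapping[str, pd.DataFrame], meta: Mapping) -> str:
    """SHA-256 over the serialized report contents and metadata; identical
    inputs give identical hashes, making reruns verifiable."""
    h = hashlib.sha256()
    h.update(json.dumps(meta, sort_keys=True, default=str).encode())
    for name in sorted(tables):
        h.update(name.encode())
        h.update(tables[name].to_csv(index=False).encode())
    return h.hexdigest()


def cohort_report(
    tables: Mapping[str, pd.DataFrame],
    meta: Mapping | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Assemble (and optionally write) the cohort report.

    ``tables`` maps section names (composition, distances, infiltration,
    checkpoint_combos, ...) to DataFrames; empty input yields an empty
    report with a warning flag in the manifest.  Returns
    ``{"tables": ..., "manifest": ...}``; when ``outdir`` is given each
    table is written as ``<name>.csv`` plus ``manifest.json``.
    """
    meta = dict(meta or {})
    manifest = {
        "sections": sorted(tables),
        "rows": {name: int(len(df)) for name, df in tables.items()},
        "meta": meta,
        "empty": not tables,
    }
    manifest["hash"] = manifest_hash(tables, manifest)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
    return {"tables": dict(tables), "manifest": manifest}
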