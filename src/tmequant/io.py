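"""Reading and writing the pipeline's plain-text tables and images.

Cell tables are CSV with the documented header (cell_id, image_id,
sample_id, site, x_um, y_um, one column per marker).  Whole-slide export
dialects (e.g. QuPath's "Centroid X µm") are translated through a column
map.  Collagen images are single-channel TIFF or PNG.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "QUPATH_COLUMN_MAP",
    "read_cell_table",
    "write_cell_table",
    "write_image",
    "read_image",
]

#: Translation of common QuPath measurement-export headers.
QUPATH_COLUMN_MAP: dict[str, str] = {
    "Object ID": "cell_id",
    "Image": "image_id",
    "Centroid X µm": "x_um",
    "Centroid Y µm": "y_um",
}

REQUIRED_COLUMNS = ("cell_id", "image_id", "x_um", "y_um")


def read_cell_table(
    path,
    column_map: Mapping[str, str] | None = None,
    sep: str = ",",
) -> pd.DataFrame:
    """Read a per-cell measurement table, renaming dialect columns.

    ``column_map`` maps source headers to canonical names and defaults to
    the QuPath dialect; canonical headers pass through untouched.
    """
    df = pd.read_csv(path, sep=sep)
    mapping = dict(QUPATH_COLUMN_MAP if column_map is None else column_map)
    df = df.rename(columns={k: v for k, v in mapping.items() if k in df.columns})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cell table lacks required columns {missing}")
    if "sample_id" not in df.columns:
        df["sample_id"] = df["image_id"]
    return df


def write_cell_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_image(image: np.ndarray, path) -> None:
    """Write a single-channel image as TIFF or PNG by extension."""
    import tifffile

    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, np.asarray(image))
    else:
        from PIL import Image

        Image.fromarray(np.asarray(image)).save(path)


def read_image(path) -> np.ndarray:
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        return tifffile.imread(path)
    from PIL import Image

    return np.asarray(Image.open(path))
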