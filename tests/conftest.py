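import pandas as pd
import pytest

from tmequant import synthgen


@pytest.fixture(scope="session")
def imaging_cfg():
    return synthgen.default_imaging_config(seed=101)


@pytest.fixture(scope="session")
def tcell_cfg():
    return synthgen.default_tcell_config(seed=102)


@pytest.fixture(scope="session")
def cytof_cfg():
    return synthgen.default_cytof_config(seed=103)


@pytest.fixture(scope="session")
def primary_image(imaging_cfg):
    """One primary-site image at the default 10,000 cells."""
    return synthgen.gen_tissue(imaging_cfg, "primary")


@pytest.fixture(scope="session")
def metastatic_image(imaging_cfg):
    return synthgen.gen_tissue(imaging_cfg, "metastatic")


@pytest.fixture(scope="session")
def control_cells(imaging_cfg):
    """20,000 unstained negative-control cells."""
    return synthgen.gen_control(imaging_cfg, 20_000)


@pytest.fixture(scope="session")
def truth_labeled(primary_image) -> pd.DataFrame:
    """Primary image with its *true* lineage labels attached (bypasses
    gating, for spatial tests that need noise-free labels)."""
    cells, truth = primary_image
    lab = cells[["cell_id", "image_id", "sample_id", "site",
                 "x_um", "y_um"]].copy()
    lab["lineage"] = truth.cells["true_label"].to_numpy()
    return lab
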