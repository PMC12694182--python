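"""Shared fixtures: a small optical configuration and a tiny generated
dataset reused by the dataset/evaluation/CLI tests."""

from __future__ import annotations

import numpy as np
import pytest

from holostain.optics import OpticalConfig
from holostain.simulate import CellPopulationSpec, sample_cell_field
from holostain.dataset import generate_dataset


@pytest.fixture(scope="session")
def small_cfg() -> OpticalConfig:
    """256x256 sensor; all physics scales with pitch, not pixel count."""
    return OpticalConfig(sensor_shape=(256, 256))


@pytest.fixture(scope="session")
def cell_spec() -> CellPopulationSpec:
    """Density matched to the 256px field (same cells/area as 200 per
    512px field)."""
    return CellPopulationSpec(cells_per_field=50)


@pytest.fixture(scope="session")
def small_field(small_cfg, cell_spec):
    return sample_cell_field(cell_spec, small_cfg, seed=7)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A miniature campaign: 1 donor + 1 unseen donor, 2 ratios, 6 crops
    per combination, 128px crops from 256px fields."""
    base = tmp_path_factory.mktemp("tiny_dataset")
    manifest = generate_dataset(
        base,
        donors=1,
        unseen_donors=1,
        ratios=(10, 50),
        crops_per_combo=6,
        crop_size=128,
        cfg=OpticalConfig(sensor_shape=(256, 256)),
        spec_template=CellPopulationSpec(cells_per_field=50),
        seed=123,
    )
    return manifest, base
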