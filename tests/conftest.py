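"""Shared fixtures: the default end-to-end run and small noiseless setups."""

from __future__ import annotations

import numpy as np
import pytest

from zonemsi.geometry import LobuleGeometry
from zonemsi.library import (
    balance_zone_totals,
    make_entry,
    packaged_library,
    write_library,
)
from zonemsi.pipeline import RunConfig, run_pipeline
from zonemsi.simulate import SyntheticConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_run():
    """One full default pipeline run (5 mice, both modes, fixed seed)."""
    return run_pipeline(RunConfig(seed=1), write_outputs=False)


def small_library(n_per_class: int = 2) -> list:
    """A tiny balanced library spanning both modes and all three zones."""
    entries = [
        make_entry("FA", 18, 2, "negative", (2.0, 0.5, 0.5), 50.0),
        make_entry("FA", 16, 0, "negative", (1.0, 1.0, 1.0), 40.0),
        make_entry("PI", 36, 3, "negative", (0.5, 2.0, 0.5), 45.0),
        make_entry("Cer", 42, 1, "negative", (0.5, 0.5, 2.0), 30.0),
        make_entry("PC", 34, 2, "positive", (2.0, 0.5, 0.5), 80.0),
        make_entry("PC", 30, 0, "positive", (0.5, 2.0, 0.5), 60.0),
        make_entry("TG", 52, 2, "positive", (0.5, 0.5, 2.0), 70.0),
        make_entry("SM", 34, 1, "positive", (1.0, 1.0, 1.0), 55.0),
    ]
    return balance_zone_totals(entries)


@pytest.fixture()
def tiny_library():
    return small_library()


@pytest.fixture()
def small_geometry():
    return LobuleGeometry(grid_shape=(24, 24))


@pytest.fixture()
def noiseless_config(tiny_library, small_geometry):
    """Two mice, no noise of any kind — intensities are exactly generative."""
    return SyntheticConfig(
        n_mice=2, library=tiny_library, geometry=small_geometry,
        mouse_sd=0.0, noise_sd=0.0, tic_sd=0.0, mass_error_ppm=0.0, seed=11)


@pytest.fixture()
def noiseless_data(noiseless_config):
    return simulate_dataset(noiseless_config)


@pytest.fixture()
def tiny_library_tsv(tmp_path, tiny_library):
    path = tmp_path / "tiny_library.tsv"
    write_library(tiny_library, path)
    return path
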