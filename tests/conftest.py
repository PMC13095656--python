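"""Shared fixtures: small rendered volumes and the expensive session-scoped
simulation/search results reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import mtlattice as mt

#: Geometry used by most small rendered fixtures
PIXEL_SIZE = 2.116
SMALL_SHAPE = (128, 272, 640)  # (nz, ny, nx): one filament along x, box 256 fits


def straight_trace_x(shape, margin=8.0):
    nz, ny, nx = shape
    y, z = (ny - 1) / 2.0, (nz - 1) / 2.0
    return np.array([[margin, y, z], [nx - 1 - margin, y, z]])


@pytest.fixture(scope="session")
def noiseless_volume():
    """Noiseless, wedge-free 41.6 Å microtubule along x with its trace."""
    params = mt.LatticeParams(monomer_spacing=41.6)
    vol, truth = mt.render_microtubule_volume(
        params, SMALL_SHAPE, PIXEL_SIZE, margin_px=8
    )
    trace = mt.FilamentTrace("mt_noiseless", straight_trace_x(SMALL_SHAPE))
    return vol, trace, params


@pytest.fixture(scope="session")
def helical_map():
    """Noiseless 13-pf lattice map built at rise 9.61 Å, twist -27.67 deg,
    filament axis along z (the helix-search geometry)."""
    params = mt.LatticeParams.from_subunit(13, 3, 9.61, subunit_twist=-27.67)
    vol, _ = mt.render_microtubule_volume(
        params, (160, 176, 176), 2.0, orientation="z", margin_px=2
    )
    return vol, params


@pytest.fixture(scope="session")
def experiment_result():
    """The two-condition synthetic experiment at its standard settings:
    10 microtubules per condition, truths 41.6 vs 43.1 Å, +/-60 degree
    wedge, SNR 0.5, fixed seed."""
    return mt.run_two_condition_experiment(mt.RunConfig(), seed=1)


@pytest.fixture
def tiny_config(tmp_path):
    """A small-but-complete RunConfig for CLI smoke tests."""
    cfg = mt.RunConfig(
        box_px=128,
        field_shape=(64, 144, 448),
        filaments_per_field=1,
        n_microtubules=2,
    )
    path = tmp_path / "config.json"
    cfg.to_json(path)
    return cfg, path
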