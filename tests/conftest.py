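"""Shared fixtures: parameter sets, phantoms and simulated matrices.

Simulation sizes are scaled down (4-8 k acquired points, 8-16 k after
zero-fill) so the whole suite stays fast; physics and processing are
identical to the full-size defaults.
"""

import numpy as np
import pytest

from dosykit import process, seqmodel, simulate


@pytest.fixture(scope="session")
def grid():
    return simulate.SimulationGrid(points=4096)


@pytest.fixture(scope="session")
def grid_fine():
    return simulate.SimulationGrid(points=8192)


@pytest.fixture(scope="session")
def trad_params():
    return seqmodel.sequence_params("traditional")


@pytest.fixture(scope="session")
def relax_params():
    return seqmodel.sequence_params("relaxation_edited")


@pytest.fixture(scope="session")
def de_params():
    return seqmodel.sequence_params("diffusion_edited")


@pytest.fixture(scope="session")
def urine_phantom():
    return simulate.build_urine_phantom(seed=1)


@pytest.fixture(scope="session")
def plasma_phantom():
    return simulate.build_plasma_phantom(seed=0)


def process_default(ds, gw=1.0, target_points=None, calibrate_mode=None):
    """Standard processing chain used across tests."""
    if target_points is None:
        target_points = 2 * ds.grid.points
    m = process.apodize_and_transform(ds, gw=gw, target_points=target_points)
    m = process.autophase(m)
    process.estimate_noise(m)
    if calibrate_mode:
        m = process.calibrate_ppm(m, mode=calibrate_mode)
    m = process.prune_water(m)
    return m


@pytest.fixture(scope="session")
def urine_matrix(urine_phantom, trad_params, grid_fine):
    ds = simulate.simulate_dataset(urine_phantom, trad_params, grid_fine, seed=1)
    return process_default(ds)


@pytest.fixture(scope="session")
def plasma_relax_matrix(plasma_phantom, relax_params, grid_fine):
    ds = simulate.simulate_dataset(plasma_phantom, relax_params, grid_fine, seed=0)
    return process_default(ds, calibrate_mode="glucose")


def species_line_table(phantom, sf_mhz=600.13):
    """(ppm, species_name) for every simulated line (water excluded)."""
    out = []
    for sp in phantom.species + ([phantom.reference] if phantom.reference else []):
        for ppm, _amp in sp.line_table(sf_mhz):
            out.append((ppm, sp.name))
    return out
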