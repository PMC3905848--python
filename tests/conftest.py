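import numpy as np
import pytest

from irif3d import (
    FocusGeometry,
    IntensityProfile,
    SimulationConfig,
    VoxelGrid,
    parse_condition_label,
    render_focus,
)
from irif3d.pipeline import measure_condition


def make_grid(extent_um=2.0, voxel_size=(0.1, 0.1, 0.1), roles=("A",)):
    """Small empty grid for single-focus rendering tests."""
    shape = tuple(int(round(extent_um / v)) for v in voxel_size)
    return VoxelGrid.empty(shape, voxel_size, roles)


def render_single(geometry_kwargs, extent_um=2.0, voxel_size=(0.1, 0.1, 0.1)):
    grid = make_grid(extent_um, voxel_size)
    centre = tuple(e / 2 for e in grid.extent)
    geom = FocusGeometry(centre=centre, **geometry_kwargs)
    render_focus(grid, geom, "A")
    return grid, geom


def gaussian_profile(peaks, sigma=0.3, step=0.05, half_um=2.5, roles=("A",)):
    """Analytic profile: sum of unit Gaussians at the given positions."""
    x = np.arange(-round(half_um / step), round(half_um / step) + 1) * step
    y = np.zeros_like(x)
    for p in peaks:
        y = y + np.exp(-((x - p) ** 2) / (2 * sigma**2))
    y = y / y.max()
    return IntensityProfile(positions=x, intensities=y[None, :], channel_roles=roles)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(n_nuclei=6)


@pytest.fixture(scope="session")
def measured_conditions(sim_config):
    """Control 8 h / 0.5 h and BRCA1-depleted presets, fully quantified.

    Shared across tests; seeds fixed so every consumer sees the same data.
    """
    return {
        "control_G2_8h": measure_condition(
            parse_condition_label("control_G2_8h"), sim_config, seed=301
        ),
        "control_G2_0.5h": measure_condition(
            parse_condition_label("control_G2_0.5h"), sim_config, seed=302
        ),
        "siBRCA1_G2_8h": measure_condition(
            parse_condition_label("siBRCA1_G2_8h"), sim_config, seed=303
        ),
    }
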