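import numpy as np
import pytest

from songtrack.geo import BathymetryGrid, GeoPoint
from songtrack.synthetic_data import (
    DASAR_X,
    DASAR_Y,
    DASAR_Z,
    SceneConfig,
    default_sensors,
    render_bearings,
    simulate_scene,
    synth_bathymetry,
)


@pytest.fixture(scope="session")
def sensors():
    return default_sensors()


@pytest.fixture(scope="session")
def slope_bathy():
    """Linear-slope bathymetry aligned with the synthetic coastline."""
    return synth_bathymetry(slope_m_per_km=50.0, extent_km=16.0, cell_km=0.25)


@pytest.fixture(scope="session")
def simple_grid():
    """Small axis-aligned grid: depth increases eastward, 10 m per node step.

    Node spacing is 0.001 deg (~0.104 km in lon at this latitude); the 0-m
    isobath is the west edge column.
    """
    lat = 20.80 + 0.001 * np.arange(21)
    lon = -156.70 + 0.001 * np.arange(31)
    depth = np.tile(10.0 * np.arange(31), (21, 1))
    return BathymetryGrid(lat, lon, depth)


@pytest.fixture(scope="session")
def small_scene(sensors):
    """Three-singer 2-h scene with bearings, shared across tests."""
    cfg = SceneConfig(seed=42, n_singers=3, duration_h=2.0)
    truth = simulate_scene(cfg)
    bearings = render_bearings(truth, cfg)
    return cfg, truth, bearings
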