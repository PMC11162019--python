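import numpy as np
import pandas as pd
import pytest

from canopylink.grid import make_fishnet
from canopylink.pointcloud import PointCloud
from canopylink.scene import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240608)


@pytest.fixture(scope="session")
def small_scene():
    """One 4 ha flat-ish block at moderate pulse density; full truth labels."""
    cfg = SceneConfig(
        extent=(0.0, 0.0, 400.0, 300.0),
        relief_amplitude=1.5,
        correlation_length=120.0,
        n_blocks=1,
        block_area_range=(4.0, 4.0),
        block_aspect_range=(1.0, 1.0),
        plots_per_block=(4, 4),
        plot_spacing=60.0,
        point_density=4.0,
        vertical_noise_sd=0.01,
        cover_samples_per_cell=800,
        seed=11,
    )
    return generate_scene(cfg)


@pytest.fixture()
def normalized_cell_cloud(rng):
    """A single-cell normalized cloud with mixed ground/canopy returns."""
    n = 400
    grid = make_fishnet((0, 0, 20, 20), 20.0)
    h = np.concatenate([np.zeros(n // 2), rng.uniform(2.5, 15.0, n - n // 2)])
    cloud = PointCloud(
        x=rng.uniform(0, 20, n),
        y=rng.uniform(0, 20, n),
        z=h + 1000.0,
        return_number=rng.integers(1, 3, n),
        height=h,
    )
    return cloud, grid
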