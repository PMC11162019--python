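import numpy as np
import pandas as pd
import pytest

from canopylink.grid import make_fishnet
from canopylink.scene import (
    SceneConfig,
    allometric_agb,
    default_endmembers,
    fractions_from_cover,
    generate_scene,
    generate_stand,
    generate_terrain,
    layout_blocks_and_plots,
    plot_agb_mgha,
    simulate_point_cloud,
    simulate_reflectance,
    true_canopy_cover,
    BAND_NAMES,
)

EXTENT = (0.0, 0.0, 400.0, 400.0)


# ---------------------------------------------------------------- terrain


def test_zero_amplitude_is_constant_plane():
    t = generate_terrain(EXTENT, relief_amplitude=0.0, seed=1)
    x = np.linspace(0, 400, 37)
    z = t.elevation(x, x[::-1])
    assert np.all(z == z[0])


def test_terrain_seeded_determinism():
    a = generate_terrain(EXTENT, 5.0, 100.0, seed=7)
    b = generate_terrain(EXTENT, 5.0, 100.0, seed=7)
    x, y = np.meshgrid(np.linspace(0, 400, 50), np.linspace(0, 400, 50))
    assert np.array_equal(a.elevation(x, y), b.elevation(x, y))


def test_terrain_range_bounded_by_twice_amplitude():
    t = generate_terrain(EXTENT, 5.0, 80.0, seed=3)
    x, y = np.meshgrid(np.linspace(0, 400, 200), np.linspace(0, 400, 200))
    z = t.elevation(x, y)
    assert z.max() - z.min() <= 10.0 + 1e-9
    assert np.all(np.isfinite(z))


def test_terrain_rejects_empty_extent():
    with pytest.raises(ValueError):
        generate_terrain((0, 0, 0, 100), 5.0)


# ---------------------------------------------------------------- stand


def test_zero_density_gives_empty_stand():
    assert len(generate_stand(EXTENT, 0.0, seed=1)) == 0


def test_all_dbh_above_truncation_minimum():
    trees = generate_stand(EXTENT, 600.0, seed=2)
    assert (trees.dbh >= 5.0).all()
    assert (trees.height > 0).all()
    assert (trees.crown_radius > 0).all()


def test_poisson_stem_count_monte_carlo():
    # density 500/ha on 10 ha: mean count over 100 seeds within 3 SD of 5000
    counts = [
        len(generate_stand((0, 0, 500, 200), 500.0, seed=s)) for s in range(100)
    ]
    se = np.sqrt(5000 / 100)
    assert abs(np.mean(counts) - 5000) < 3 * se


def test_stand_rejects_invalid_distribution():
    with pytest.raises(ValueError):
        generate_stand(EXTENT, 100.0, {"shape": -1.0}, seed=0)
    with pytest.raises(ValueError):
        generate_stand(EXTENT, -5.0)


# ---------------------------------------------------------------- allometry


def test_allometry_identity_coefficients():
    assert allometric_agb(1.0, 1.0, 1.0, 1.0) == pytest.approx(1.0)


def test_allometry_doubling_dbh_quadruples_at_b1():
    assert allometric_agb(20.0, 10.0, 0.5, 1.0) == pytest.approx(
        4 * allometric_agb(10.0, 10.0, 0.5, 1.0)
    )


def test_allometry_hand_computed_value():
    # a=0.1, b=0.9, dbh=20, h=15 -> 0.1 * (20^2*15)^0.9 = 0.1 * 6000^0.9
    assert allometric_agb(20.0, 15.0, 0.1, 0.9) == pytest.approx(0.1 * 6000**0.9)


def test_allometry_rejects_nonpositive():
    with pytest.raises(ValueError):
        allometric_agb(-1.0, 10.0)
    with pytest.raises(ValueError):
        allometric_agb(10.0, 10.0, coeff_a=0.0)


def test_plot_agb_invariant_to_tree_ordering(rng):
    trees = generate_stand(EXTENT, 500.0, seed=5)
    shuffled = trees.sample(frac=1.0, random_state=1).reset_index(drop=True)
    a = plot_agb_mgha(trees, 200.0, 200.0)
    b = plot_agb_mgha(shuffled, 200.0, 200.0)
    assert a == pytest.approx(b)


# ---------------------------------------------------------------- point cloud


def test_treeless_cloud_is_all_ground_near_terrain():
    terrain = generate_terrain(EXTENT, 2.0, 100.0, seed=4)
    empty = generate_stand(EXTENT, 0.0, seed=1)
    cloud = simulate_point_cloud(empty, terrain, 0.5, seed=9, vertical_noise_sd=0.05)
    assert set(cloud.truth_class) == {"ground"}
    dz = cloud.z - terrain.elevation(cloud.x, cloud.y)
    assert np.abs(dz).max() < 6 * 0.05


def test_realized_density_close_to_requested():
    terrain = generate_terrain((0, 0, 40, 40), 0.0, seed=0)
    trees = generate_stand((0, 0, 40, 40), 400.0, seed=3)
    cloud = simulate_point_cloud(trees, terrain, 300.0, canopy_penetration=0.0, seed=5)
    realized = len(cloud) / (40 * 40)
    assert abs(realized - 300.0) / 300.0 < 0.05


def test_crown_hits_bounded_by_max_tree_height():
    terrain = generate_terrain(EXTENT, 0.0, seed=0)
    trees = generate_stand(EXTENT, 500.0, seed=6)
    sd = 0.05
    cloud = simulate_point_cloud(trees, terrain, 2.0, vertical_noise_sd=sd, seed=7)
    canopy = cloud.truth_class == "canopy"
    h = cloud.z[canopy] - terrain.elevation(cloud.x[canopy], cloud.y[canopy])
    assert h.max() <= trees.height.max() + 3 * sd


def test_cloud_seeded_determinism():
    terrain = generate_terrain(EXTENT, 2.0, 100.0, seed=1)
    trees = generate_stand(EXTENT, 300.0, seed=2)
    a = simulate_point_cloud(trees, terrain, 1.0, seed=42)
    b = simulate_point_cloud(trees, terrain, 1.0, seed=42)
    assert np.array_equal(a.z, b.z) and np.array_equal(a.return_number, b.return_number)


def test_cover_truth_matches_crown_hit_fraction():
    """Vertical-projection cover and simulated first-return crown fraction
    agree within a 99% binomial interval."""
    extent = (0, 0, 60, 60)
    terrain = generate_terrain(extent, 0.0, seed=0)
    trees = generate_stand(extent, 700.0, seed=8)
    grid = make_fishnet(extent, 20.0)
    cover = true_canopy_cover(trees, grid, grid.all_cell_ids(), 200_000, seed=1)
    cloud = simulate_point_cloud(trees, terrain, 300.0, canopy_penetration=0.0, seed=2)
    ids = grid.point_to_cell(cloud.x, cloud.y)
    first = cloud.return_number == 1
    for j, cid in enumerate(grid.all_cell_ids()):
        sel = first & (ids == cid)
        n1 = sel.sum()
        p_hat = (cloud.truth_class[sel] == "canopy").mean()
        p = cover[j]
        se = np.sqrt(p * (1 - p) * (1 / n1 + 1 / 200_000))
        assert abs(p_hat - p) < 2.58 * se + 1e-6


# ---------------------------------------------------------------- reflectance


def test_pure_gv_cell_reproduces_gv_spectrum():
    lib = default_endmembers()
    truth = pd.DataFrame({"GV": [1.0], "NPV": [0.0], "Soil": [0.0], "Shade": [0.0]})
    refl = simulate_reflectance(truth, lib, band_noise_sd=0.0)
    assert np.allclose(refl[list(BAND_NAMES)].to_numpy()[0], lib.spectra["GV"])


def test_linear_mixing_is_arithmetic_mean():
    lib = default_endmembers()
    truth = pd.DataFrame({"GV": [0.5], "NPV": [0.0], "Soil": [0.5], "Shade": [0.0]})
    refl = simulate_reflectance(truth, lib, band_noise_sd=0.0)
    expected = (np.asarray(lib.spectra["GV"]) + np.asarray(lib.spectra["Soil"])) / 2
    assert np.allclose(refl[list(BAND_NAMES)].to_numpy()[0], expected)


def test_noisy_reflectance_stays_in_unit_interval():
    cover = np.linspace(0, 1, 200)
    truth = fractions_from_cover(cover)
    refl = simulate_reflectance(truth, band_noise_sd=0.05, seed=3)
    vals = refl[list(BAND_NAMES)].to_numpy()
    assert vals.min() >= 0.0 and vals.max() <= 1.0


def test_fractions_sum_to_one_and_nonnegative():
    fr = fractions_from_cover(np.linspace(0, 1, 500))
    total = fr.sum(axis=1).to_numpy()
    assert np.all(np.abs(total - 1.0) < 1e-12)
    assert (fr.to_numpy() >= 0).all()


# ---------------------------------------------------------------- layout


def test_default_layout_plot_contract():
    grid = make_fishnet((0, 0, 9000, 9000), 20.0)
    blocks, plots = layout_blocks_and_plots(grid, seed=5, allow_fewer_plots=True)
    assert len(blocks) == 10
    # strict 250 m minimum spacing caps 30-50 ha blocks below the 10-12
    # plot target; the layout fills each block to its packing capacity
    assert len(plots) >= 50
    # every plot centre is a grid-cell centre
    cx, cy = grid.cell_center(plots.cell_id.to_numpy())
    assert np.allclose(cx, plots.x) and np.allclose(cy, plots.y)
    # pairwise spacing within each block
    for _, g in plots.groupby("block_id"):
        p = g[["x", "y"]].to_numpy()
        d = np.linalg.norm(p[:, None] - p[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 250.0 - 1e-6
    # buffer from block border
    joined = plots.merge(blocks, on="block_id")
    assert (joined.x - joined.xmin).min() >= 50 - 1e-6
    assert (joined.xmax - joined.x).min() >= 50 - 1e-6
    assert (joined.y - joined.ymin).min() >= 50 - 1e-6
    assert (joined.ymax - joined.y).min() >= 50 - 1e-6


def test_infeasible_packing_reports_achieved_count():
    grid = make_fishnet((0, 0, 300, 300), 20.0)
    with pytest.raises(ValueError, match="achieved"):
        layout_blocks_and_plots(
            grid, n_blocks=2, block_area_range=(4.0, 4.0),
            plots_per_block=(30, 30), plot_spacing=60.0, border_buffer=50.0,
            seed=0,
        )


# ---------------------------------------------------------------- whole scene


def test_scene_seeded_determinism(small_scene):
    again = generate_scene(small_scene.config)
    pd.testing.assert_frame_equal(small_scene.trees, again.trees)
    pd.testing.assert_frame_equal(small_scene.reflectance, again.reflectance)
    assert np.array_equal(small_scene.cloud.z, again.cloud.z)


def test_scene_truth_invariants(small_scene):
    t = small_scene.truth
    total = t[["GV", "NPV", "Soil", "Shade"]].sum(axis=1)
    assert np.all(np.abs(total - 1.0) < 1e-12)
    assert t.cover.between(0, 1).all()
    assert (t.agb_mgha >= 0).all()
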