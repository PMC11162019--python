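import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from canopylink.grid import make_fishnet
from canopylink.selection import SubsetModel
from canopylink.twophase import (
    AgbSeries,
    PhaseModel,
    SOURCE_FIELD,
    SOURCE_LIDAR_PRED,
    SelectionConfig,
    evaluate,
    fit_direct,
    fit_phase1,
    fit_phase2,
    predict_cells,
    remove_margin_cells,
    sample_reference_cells,
)


def _stub_model(coefs, intercept, transform):
    sm = SubsetModel(
        predictors=tuple(coefs), intercept=intercept, coefficients=coefs,
        n=0, p=len(coefs), sse=np.nan, r2=np.nan, adj_r2=np.nan,
        pred_r2=np.nan, press=np.nan, cp=np.nan, aicc=np.nan, bic=np.nan,
        rmse=np.nan,
    )
    return PhaseModel("ground_lidar", transform, sm, None, {})


# ---------------------------------------------------------- margin cells


def test_aligned_block_keeps_all_cells():
    grid = make_fishnet((0, 0, 200, 200), 20.0)
    blk = box(20, 20, 120, 120)  # exactly 5x5 cells
    kept = remove_margin_cells(grid, grid.all_cell_ids(), blk)
    assert kept.size == 25


def test_shifted_block_drops_straddlers():
    grid = make_fishnet((0, 0, 200, 200), 20.0)
    kept_aligned = remove_margin_cells(grid, grid.all_cell_ids(), box(20, 20, 120, 120))
    kept_shifted = remove_margin_cells(grid, grid.all_cell_ids(), box(30, 20, 130, 120))
    assert kept_shifted.size == 20  # one column of straddlers on each side
    assert kept_aligned.size > kept_shifted.size


def test_margin_cells_fully_contained():
    grid = make_fishnet((0, 0, 200, 200), 20.0)
    blk = box(15, 27, 143, 161)
    kept = remove_margin_cells(grid, grid.all_cell_ids(), blk)
    for cid in kept:
        assert blk.covers(box(*grid.cell_bounds(cid)))


# ---------------------------------------------------------- prediction


def test_ln_model_hand_arithmetic():
    model = _stub_model(
        {"CC": 1.68, "H80": 0.08, "D20": 5.32, "Hcv": -2.97}, 0.20, "ln"
    )
    feats = pd.DataFrame(
        {"cell_id": [0], "CC": [0.8], "H80": [12.0], "D20": [0.6], "Hcv": [0.4]}
    )
    pred = predict_cells(model, feats)
    # ln(AGB) = 0.2 + 1.344 + 0.96 + 3.192 - 1.188 = 4.508
    assert pred.values[0] == pytest.approx(np.exp(4.508), rel=1e-9)
    assert pred.values[0] == pytest.approx(90.7, abs=0.1)
    assert pred.source == SOURCE_LIDAR_PRED


def test_identity_model_hand_arithmetic():
    model = _stub_model(
        {"B11": 2778.0, "GNDVI": 1084.0, "LAI": 59.1}, -1171.0, "identity"
    )
    feats = pd.DataFrame(
        {"cell_id": [0], "B11": [0.3], "GNDVI": [0.5], "LAI": [2.0]}
    )
    pred = predict_cells(model, feats)
    assert pred.values[0] == pytest.approx(322.6, abs=1e-9)


def test_constant_model_and_nonnegativity():
    model = _stub_model({"x": 0.0}, -5.0, "identity")
    feats = pd.DataFrame({"cell_id": range(4), "x": [1.0, 2.0, 3.0, 4.0]})
    pred = predict_cells(model, feats)
    assert np.all(pred.values == 0.0)  # negative intercept clamped


def test_missing_predictor_named():
    model = _stub_model({"CC": 1.0}, 0.0, "ln")
    with pytest.raises(ValueError, match="CC"):
        predict_cells(model, pd.DataFrame({"cell_id": [0], "H80": [1.0]}))


# ---------------------------------------------------------- sampling


def test_exhaustive_draw_returns_every_cell():
    series = AgbSeries(np.arange(30), np.linspace(1, 30, 30), SOURCE_LIDAR_PRED)
    ref = sample_reference_cells(series, 30, seed=3)
    assert set(ref.cell_id) == set(range(30))


def test_sampling_seeded_determinism():
    series = AgbSeries(np.arange(100), np.arange(100, dtype=float), SOURCE_LIDAR_PRED)
    a = sample_reference_cells(series, 40, seed=9)
    b = sample_reference_cells(series, 40, seed=9)
    assert np.array_equal(a.cell_id, b.cell_id)


def test_sampling_inclusion_frequency_uniform():
    series = AgbSeries(np.arange(20), np.arange(20, dtype=float), SOURCE_LIDAR_PRED)
    counts = np.zeros(20)
    n_draws, k = 1000, 5
    for s in range(n_draws):
        ref = sample_reference_cells(series, k, seed=s)
        counts[ref.cell_id] += 1
    p = k / 20
    se = np.sqrt(p * (1 - p) * n_draws)
    assert np.abs(counts - n_draws * p).max() < 4 * se


def test_oversampling_rejected():
    series = AgbSeries(np.arange(10), np.arange(10, dtype=float), SOURCE_LIDAR_PRED)
    with pytest.raises(ValueError, match="10"):
        sample_reference_cells(series, 11)


# ---------------------------------------------------------- firewall


def test_phase2_refuses_field_agb():
    field = AgbSeries([0], [10.0], SOURCE_FIELD)
    with pytest.raises(ValueError, match="lidar"):
        fit_phase2(field, pd.DataFrame({"cell_id": [0], "NDVI": [0.5]}))


def test_direct_refuses_lidar_predictions():
    pred = AgbSeries([0], [10.0], SOURCE_LIDAR_PRED)
    with pytest.raises(ValueError, match="field"):
        fit_direct(pred, pd.DataFrame({"cell_id": [0], "NDVI": [0.5]}))


def test_unknown_source_rejected():
    with pytest.raises(ValueError):
        AgbSeries([0], [1.0], "guess")


# ---------------------------------------------------------- recovery fits


def _synthetic_feature_frame(rng, n):
    return pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "CC": rng.uniform(0.2, 0.9, n),
            "H80": rng.uniform(4.0, 16.0, n),
            "D20": rng.uniform(0.1, 0.8, n),
            "Hcv": rng.uniform(0.2, 1.2, n),
            "noise1": rng.standard_normal(n),
            "noise2": rng.standard_normal(n),
        }
    )


def test_phase1_noiseless_recovery_to_1e6():
    rng = np.random.default_rng(17)
    feats = _synthetic_feature_frame(rng, 60)
    ln_agb = (0.2 + 1.68 * feats.CC + 0.08 * feats.H80
              + 5.32 * feats.D20 - 2.97 * feats.Hcv)
    plots = AgbSeries(feats.cell_id.to_numpy(), np.exp(ln_agb), SOURCE_FIELD)
    model = fit_phase1(plots, feats, SelectionConfig(cv_folds=5))
    assert set(model.model.predictors) == {"CC", "H80", "D20", "Hcv"}
    assert model.model.coefficients["CC"] == pytest.approx(1.68, abs=1e-6)
    assert model.model.coefficients["H80"] == pytest.approx(0.08, abs=1e-6)
    assert model.model.coefficients["D20"] == pytest.approx(5.32, abs=1e-6)
    assert model.model.coefficients["Hcv"] == pytest.approx(-2.97, abs=1e-6)
    assert model.model.intercept == pytest.approx(0.20, abs=1e-6)


def test_direct_noiseless_identity_recovery():
    rng = np.random.default_rng(23)
    n = 60
    feats = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "B11": rng.uniform(0.1, 0.5, n),
            "GNDVI": rng.uniform(0.2, 0.9, n),
            "LAI": rng.uniform(0.5, 5.0, n),
            "junk": rng.standard_normal(n),
        }
    )
    agb = (2778 * feats.B11 + 1084 * feats.GNDVI + 59.1 * feats.LAI - 1171).to_numpy()
    plots = AgbSeries(feats.cell_id.to_numpy(), agb, SOURCE_FIELD)
    model = fit_direct(plots, feats, SelectionConfig(cv_folds=5))
    assert set(model.model.predictors) == {"B11", "GNDVI", "LAI"}
    assert model.model.coefficients["B11"] == pytest.approx(2778, abs=1e-6)
    assert model.model.intercept == pytest.approx(-1171, abs=1e-6)


def test_phase1_requires_minimum_plots():
    rng = np.random.default_rng(3)
    feats = _synthetic_feature_frame(rng, 10)
    plots = AgbSeries(feats.cell_id.to_numpy(), rng.uniform(20, 80, 10), SOURCE_FIELD)
    with pytest.raises(ValueError, match="20"):
        fit_phase1(plots, feats)


# ---------------------------------------------------------- evaluation


def test_perfect_predictions():
    rep = evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], label="t")
    assert rep.rmse == 0.0 and rep.bias == 0.0 and rep.r2 == pytest.approx(1.0)


def test_constant_offset_bias():
    obs = np.array([10.0, 20.0, 30.0])
    rep = evaluate(obs + 2.0, obs, label="t")
    assert rep.bias == pytest.approx(2.0)
    assert rep.rmse == pytest.approx(2.0)


def test_two_point_hand_example():
    rep = evaluate([110.0, 40.0], [100.0, 50.0], label="t")
    assert rep.rmse == pytest.approx(10.0)
    assert rep.rrmse == pytest.approx(100 * 10 / 75)  # 13.33%
    assert rep.bias == pytest.approx(0.0)
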