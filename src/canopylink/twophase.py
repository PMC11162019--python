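"""Two-phase biomass estimation: plots -> lidar -> satellite.

Phase 1 regresses ln(field-plot AGB) on per-cell lidar metrics, predicts
AGB for every interior grid cell of the lidar blocks, and a random sample
of those lidar-predicted cells becomes the phase-2 reference set.  Phase 2
regresses ln(lidar-predicted AGB) on wall-to-wall satellite metrics.  A
direct plot-to-satellite model (identity response) is the baseline.

An information firewall is enforced through :class:`AgbSeries` source tags:
phase-2 training only accepts lidar-predicted AGB and the direct model only
accepts field AGB.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box
from shapely.prepared import prep

from canopylink.grid import GridFramework
from canopylink.selection import (
    SelectionTable,
    SubsetModel,
    best_subsets,
    independent_columns,
    kfold_cv,
    pearson_prefilter,
)

SOURCE_FIELD = "field"
SOURCE_LIDAR_PRED = "lidar_pred"


@dataclass
class AgbSeries:
    """AGB values (Mg/ha) keyed by grid cell, tagged with their provenance.

    ``source`` is either ``"field"`` (plot measurements) or ``"lidar_pred"``
    (phase-1 model predictions); the tag enforces the two-phase data flow.
    """

    cell_id: np.ndarray
    values: np.ndarray
    source: str

    def __post_init__(self):
        self.cell_id = np.asarray(self.cell_id, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.cell_id.size != self.values.size:
            raise ValueError("cell_id and values must have equal length")
        if self.source not in (SOURCE_FIELD, SOURCE_LIDAR_PRED):
            raise ValueError(f"unknown AGB source {self.source!r}")

    def __len__(self):
        return self.values.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.cell_id, "agb_mgha": self.values})


@dataclass(frozen=True)
class SelectionConfig:
    correlation_threshold: float = 0.85
    max_subset_size: int = 10
    cv_folds: int = 10
    cv_seed: int = 0
    smearing_correction: bool = False  # back-transform bias correction, off by default


@dataclass
class PhaseModel:
    """A fitted phase model: selection table, chosen subset, CV report.

    ``response_ceiling`` truncates predictions to the calibration range
    (1.5x the largest training response): a linear ln-model extrapolated
    beyond the plot data can otherwise return physically absurd AGB.
    """

    tag: str  # ground_lidar | lidar_sentinel | ground_sentinel
    transform: str  # "ln" | "identity"
    model: SubsetModel
    selection: SelectionTable
    cv: dict
    smearing_factor: float = 1.0
    response_ceiling: float = np.inf

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        raw = self.model.predict(features)
        if self.transform == "ln":
            raw = np.exp(raw) * self.smearing_factor
        return np.minimum(raw, self.response_ceiling)


@dataclass
class EvaluationReport:
    """Accuracy summary of predicted vs observed AGB (report-table row)."""

    model: str
    r2: float
    adj_r2: float
    pred_r2: float
    rmse: float
    rrmse: float
    bias: float
    n: int

    def to_dict(self) -> dict:
        return {
            "model": self.model, "R2": self.r2, "adj_R2": self.adj_r2,
            "pred_R2": self.pred_r2, "RMSE_Mg_ha": self.rmse,
            "rRMSE_pct": self.rrmse, "bias_Mg_ha": self.bias, "n": self.n,
        }


# ---------------------------------------------------------------------------
# spatial helpers
# ---------------------------------------------------------------------------


def remove_margin_cells(grid: GridFramework, cell_ids, block_polygon) -> np.ndarray:
    """Retain only the cells fully contained in the block polygon.

    Blocks rarely align with the grid; margin cells covering only part of a
    cell would mix inside/outside returns, so they are dropped.
    """
    cell_ids = np.asarray(cell_ids, dtype=np.int64)
    prepared = prep(block_polygon)
    keep = np.array(
        [prepared.covers(box(*grid.cell_bounds(cid))) for cid in cell_ids],
        dtype=bool,
    )
    if not keep.any():
        warnings.warn("no cells fully inside the block polygon")
    return cell_ids[keep]


def sample_reference_cells(cell_predictions: AgbSeries, n: int = 700, seed: int = 0) -> AgbSeries:
    """Uniform sample (without replacement) of lidar-predicted cells."""
    pool = len(cell_predictions)
    if n > pool:
        raise ValueError(f"requested {n} reference cells but only {pool} available")
    rng = np.random.default_rng(seed)
    idx = rng.choice(pool, size=n, replace=False)
    return AgbSeries(
        cell_predictions.cell_id[idx],
        cell_predictions.values[idx],
        cell_predictions.source,
    )


# ---------------------------------------------------------------------------
# phase fits
# ---------------------------------------------------------------------------

LN_FLOOR_MGHA = 0.5  # responses below this are excluded from ln fits
MIN_TRAIN_SPREAD_RATIO = 0.35  # training SD / prediction-table SD screen


def _fit_phase(
    response: AgbSeries,
    features: pd.DataFrame,
    tag: str,
    transform: str,
    config: SelectionConfig,
    min_n: int = 20,
) -> PhaseModel:
    data = response.to_frame().merge(features, on="cell_id", how="inner")
    if transform == "ln":
        low = data["agb_mgha"] < LN_FLOOR_MGHA
        if low.any():
            warnings.warn(
                f"{int(low.sum())} observations below {LN_FLOOR_MGHA} Mg/ha "
                "excluded from the ln fit"
            )
            data = data[~low]
        y = np.log(data["agb_mgha"].to_numpy(float))
    else:
        y = data["agb_mgha"].to_numpy(float)
    n = len(data)
    if n < min_n:
        raise ValueError(f"{tag}: only {n} observations; need >= {min_n} for selection")

    bookkeeping = {"cell_id", "x_center", "y_center", "n_points", "agb_mgha",
                   "unmix_residual"}
    feature_names = [c for c in features.columns if c not in bookkeeping]
    data = data.dropna(axis=1, how="any")
    feature_names = [c for c in feature_names if c in data.columns]
    # applicability-domain screen: a predictor whose spread in the training
    # sample is a sliver of its spread over the prediction table would get a
    # huge, extrapolation-hostile coefficient (fatal for ln-response models);
    # such predictors are excluded from the candidate pool.
    screened = []
    for c in feature_names:
        sd_all = float(features[c].std())
        sd_train = float(data[c].std())
        if sd_all > 0 and sd_train / sd_all < MIN_TRAIN_SPREAD_RATIO:
            screened.append(c)
    if screened:
        warnings.warn(
            f"{tag}: excluded predictors poorly spanned by the training sample: "
            f"{screened}"
        )
        feature_names = [c for c in feature_names if c not in screened]
    retained = pearson_prefilter(data[feature_names], y, config.correlation_threshold)
    # drop exact linear dependences the pairwise screen cannot detect
    # (e.g. all four endmember fractions, which sum to one)
    indep = independent_columns(data, retained)
    if len(indep) < len(retained):
        warnings.warn(
            f"{tag}: dropped exactly collinear predictors "
            f"{sorted(set(retained) - set(indep))}"
        )
        retained = indep
    # keep the candidate pool small enough for the full-model criteria
    cap = max(n - 5, 1)
    if len(retained) > cap:
        key = {
            c: abs(np.corrcoef(data[c].to_numpy(float), y)[0, 1]) for c in retained
        }
        retained = sorted(retained, key=lambda c: -key[c])[:cap]
    table = best_subsets(data[retained], y, config.max_subset_size)
    model = table.selected
    cv = kfold_cv(data, y, model.predictors, k=min(config.cv_folds, n), seed=config.cv_seed)

    smear = 1.0
    if transform == "ln" and config.smearing_correction:
        fitted = model.predict(data)
        smear = float(np.mean(np.exp(y - fitted)))
    ceiling = 1.5 * float(data["agb_mgha"].max())
    return PhaseModel(tag, transform, model, table, cv, smear, ceiling)


def fit_phase1(
    plot_agb: AgbSeries, lidar_features: pd.DataFrame, config: SelectionConfig = SelectionConfig()
) -> PhaseModel:
    """Phase 1: ln(field-plot AGB) against per-cell lidar metrics."""
    if plot_agb.source != SOURCE_FIELD:
        raise ValueError("phase-1 response must be field plot AGB")
    return _fit_phase(plot_agb, lidar_features, "ground_lidar", "ln", config)


def fit_phase2(
    reference_agb: AgbSeries,
    sentinel_features: pd.DataFrame,
    config: SelectionConfig = SelectionConfig(),
) -> PhaseModel:
    """Phase 2: ln(lidar-predicted AGB) against satellite metrics.

    Refuses field AGB: the two-phase firewall requires phase 2 to train on
    lidar predictions only.
    """
    if reference_agb.source != SOURCE_LIDAR_PRED:
        raise ValueError("phase-2 response must be lidar-predicted AGB")
    return _fit_phase(reference_agb, sentinel_features, "lidar_sentinel", "ln", config)


def fit_direct(
    plot_agb: AgbSeries,
    sentinel_features: pd.DataFrame,
    config: SelectionConfig = SelectionConfig(),
) -> PhaseModel:
    """Direct baseline: field-plot AGB against satellite metrics (identity)."""
    if plot_agb.source != SOURCE_FIELD:
        raise ValueError("direct model response must be field plot AGB")
    return _fit_phase(plot_agb, sentinel_features, "ground_sentinel", "identity", config)


def predict_cells(model: PhaseModel, feature_table: pd.DataFrame) -> AgbSeries:
    """Per-cell AGB predictions (Mg/ha, non-negative) from a phase model."""
    pred = model.predict(feature_table)
    pred = np.maximum(pred, 0.0)
    cell_id = (
        feature_table["cell_id"].to_numpy()
        if "cell_id" in feature_table.columns
        else np.arange(len(feature_table))
    )
    return AgbSeries(cell_id, pred, SOURCE_LIDAR_PRED)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def evaluate(predictions, observations, model: PhaseModel | None = None, label: str = "") -> EvaluationReport:
    """RMSE / rRMSE / bias / R^2 of paired predicted and observed AGB."""
    pred = np.asarray(predictions, dtype=float)
    obs = np.asarray(observations, dtype=float)
    if pred.size != obs.size or pred.size < 2:
        raise ValueError("need paired vectors with n >= 2")
    resid = pred - obs
    rmse = float(np.sqrt((resid**2).mean()))
    mean_obs = obs.mean()
    rrmse = 100.0 * rmse / mean_obs if mean_obs != 0 else np.nan
    sst = ((obs - mean_obs) ** 2).sum()
    r2 = 1.0 - float((resid**2).sum() / sst) if sst > 0 else np.nan
    return EvaluationReport(
        model=label or (model.tag if model else ""),
        r2=model.model.r2 if model else r2,
        adj_r2=model.model.adj_r2 if model else np.nan,
        pred_r2=r2 if model else np.nan,
        rmse=rmse,
        rrmse=rrmse,
        bias=float(resid.mean()),
        n=pred.size,
    )


def cv_evaluation(model: PhaseModel, response: AgbSeries, features: pd.DataFrame,
                  config: SelectionConfig) -> EvaluationReport:
    """Out-of-fold evaluation on the Mg/ha scale.

    Refits the chosen predictors under k-fold CV, back-transforms ln-scale
    predictions, and reports RMSE/rRMSE/bias against the observed AGB.
    R^2 and adjusted R^2 are the training values on the model scale;
    pred-R^2 is the cross-validated R^2 on the Mg/ha scale.
    """
    data = response.to_frame().merge(features, on="cell_id", how="inner")
    if model.transform == "ln":
        data = data[data["agb_mgha"] >= LN_FLOOR_MGHA]
        y_fit = np.log(data["agb_mgha"].to_numpy(float))
    else:
        y_fit = data["agb_mgha"].to_numpy(float)
    cv = kfold_cv(data, y_fit, model.model.predictors,
                  k=min(config.cv_folds, len(data)), seed=config.cv_seed)
    pred = cv["predictions"]
    if model.transform == "ln":
        pred = np.exp(pred) * model.smearing_factor
    pred = np.minimum(pred, model.response_ceiling)
    obs = data["agb_mgha"].to_numpy(float)
    rep = evaluate(pred, obs, label=model.tag)
    rep.pred_r2 = rep.r2  # cross-validated R^2 on the Mg/ha scale
    rep.r2 = model.model.r2
    rep.adj_r2 = model.model.adj_r2
    return rep


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config, out_dir=None, log=None):
    """Run the whole study on one seeded configuration.

    Stages: scene generation -> point-cloud preprocessing -> lidar metrics
    -> phase-1 fit -> block-cell prediction -> reference sampling ->
    satellite features -> phase-2 fit -> direct fit -> evaluation ->
    wall-to-wall AGB map.  Returns a dict with the three evaluation reports
    (plus against-truth twins), the phase models, the AGB map array and the
    intermediate tables.  ``out_dir`` writes the standard artifacts
    (report_table5.csv, selection_*.csv, agb_map.tif/.tfw/.csv).

    Any stage failure is re-raised with the stage name for context.
    """
    from canopylink import io as clio
    from canopylink.lidar_metrics import extract_cell_metrics
    from canopylink.pointcloud import normalize_against_terrain, preprocess
    from canopylink.scene import generate_scene
    from canopylink.spectral import spectral_feature_table

    def _log(msg):
        if log:
            log(msg)

    stage = "scene generation"
    try:
        scene = generate_scene(config.scene)
        _log(f"scene: {len(scene.trees)} trees, {len(scene.plots)} plots, "
             f"{len(scene.blocks)} blocks, seed={config.scene.seed}")

        stage = "point-cloud preprocessing"
        pp = config.preprocessing
        if pp.mode == "truth":
            cloud = normalize_against_terrain(scene.cloud, scene.terrain)
        else:
            cloud, _dtm = preprocess(
                scene.cloud,
                k_neighbors=pp.k_neighbors,
                sd_multiplier=pp.sd_multiplier,
                seed_cell_size=pp.seed_cell_size,
                max_angle_deg=pp.max_angle_deg,
                max_distance=pp.max_distance,
                dtm_resolution=pp.dtm_resolution,
                idw_power=pp.idw_power,
                idw_neighbors=pp.idw_neighbors,
            )
        _log(f"preprocessing ({pp.mode}): {len(cloud)} points normalized")

        stage = "lidar metric extraction"
        lidar_features, under = extract_cell_metrics(cloud, scene.grid, config.metrics)
        _log(f"lidar metrics: {len(lidar_features)} cells "
             f"({len(under)} under the point minimum)")

        stage = "phase-1 fit"
        plots = scene.plots
        plot_agb = AgbSeries(
            plots["cell_id"].to_numpy(), plots["agb_mgha"].to_numpy(), SOURCE_FIELD
        )
        phase1 = fit_phase1(plot_agb, lidar_features, config.selection)
        _log(f"phase 1 selected {list(phase1.model.predictors)} "
             f"(R2={phase1.model.r2:.3f})")

        stage = "block-cell prediction"
        block_ids = []
        for _, blk in scene.blocks.iterrows():
            poly = box(blk.xmin, blk.ymin, blk.xmax, blk.ymax)
            ids = remove_margin_cells(
                scene.grid, lidar_features["cell_id"].to_numpy(), poly
            )
            block_ids.append(ids)
        block_ids = np.unique(np.concatenate(block_ids))
        block_features = lidar_features[lidar_features["cell_id"].isin(block_ids)]
        cell_pred = predict_cells(phase1, block_features)
        _log(f"phase 1 predicted {len(cell_pred)} interior block cells")

        stage = "reference sampling"
        n_ref = min(config.sampling.n_reference, len(cell_pred))
        if n_ref < config.sampling.n_reference:
            warnings.warn(
                f"reference sample capped at pool size {n_ref} "
                f"(requested {config.sampling.n_reference})"
            )
        reference = sample_reference_cells(cell_pred, n_ref, seed=config.scene.seed + 1)

        stage = "satellite features"
        truth_arg = (
            scene.truth if config.sampling.biophysical_mode == "truth" else None
        )
        sat_features = spectral_feature_table(
            scene.reflectance,
            scene_truth=truth_arg,
            biophysical_noise_sd=config.sampling.biophysical_noise_sd,
            seed=config.scene.seed + 2,
        )

        stage = "phase-2 fit"
        phase2 = fit_phase2(reference, sat_features, config.selection)
        _log(f"phase 2 selected {list(phase2.model.predictors)} "
             f"(R2={phase2.model.r2:.3f})")

        stage = "direct fit"
        direct = fit_direct(plot_agb, sat_features, config.selection)
        _log(f"direct model selected {list(direct.model.predictors)} "
             f"(R2={direct.model.r2:.3f})")

        stage = "evaluation"
        reports = [
            cv_evaluation(phase1, plot_agb, lidar_features, config.selection),
            cv_evaluation(phase2, reference, sat_features, config.selection),
            cv_evaluation(direct, plot_agb, sat_features, config.selection),
        ]
        # against-truth twins (synthetic mode only): same predictions, but
        # scored against the scene's true cell AGB -- labelled to avoid
        # conflation with the reports above.
        truth_by_cell = scene.truth.set_index("cell_id")["agb_mgha"]
        truth_reports = []
        ref_truth = truth_by_cell.reindex(reference.cell_id).to_numpy()
        p2_pred = phase2.predict(
            sat_features.set_index("cell_id").loc[reference.cell_id].reset_index()
        )
        truth_reports.append(
            evaluate(p2_pred, ref_truth, label="lidar_sentinel_vs_truth")
        )
        p1_truth = truth_by_cell.reindex(cell_pred.cell_id).to_numpy()
        truth_reports.append(
            evaluate(cell_pred.values, p1_truth, label="ground_lidar_vs_truth")
        )

        stage = "AGB map"
        grid = scene.grid
        agb_map = np.full((grid.n_rows, grid.n_cols), -9999.0, dtype=np.float32)
        mappable = sat_features.dropna(subset=list(phase2.model.predictors))
        map_pred = phase2.predict(mappable)
        rows, cols = grid.cell_rowcol(mappable["cell_id"].to_numpy())
        agb_map[rows, cols] = np.maximum(map_pred, 0.0)

        result = {
            "scene": scene,
            "lidar_features": lidar_features,
            "sat_features": sat_features,
            "phase1": phase1,
            "phase2": phase2,
            "direct": direct,
            "cell_predictions": cell_pred,
            "reference": reference,
            "reports": reports,
            "truth_reports": truth_reports,
            "agb_map": agb_map,
        }

        if out_dir is not None:
            stage = "writing outputs"
            clio.write_run_outputs(result, grid, out_dir)
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage: {stage}") from exc


def report_frame(reports) -> pd.DataFrame:
    """Stack evaluation reports into the summary-table layout."""
    return pd.DataFrame([r.to_dict() for r in reports])
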