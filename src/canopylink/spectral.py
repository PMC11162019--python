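"""Satellite metrics: vegetation indices, endmember unmixing, NDFI.

Works on per-cell reflectance in bands B2..B12 (surface reflectance, 0-1).
The fraction images come from fully constrained least squares (FCLS)
unmixing — non-negative fractions summing to one — against a four-endmember
library (green vegetation GV, non-photosynthetic vegetation NPV, soil,
shade).  The normalized difference fraction index contrasts the
shade-normalized GV fraction against NPV + soil:

    GV_shade = GV / (1 + Shade)
    NDFI     = (GV_shade - (NPV + Soil)) / (GV_shade + (NPV + Soil))

Biophysical variables (LAI, FAPAR, FCOVER, CAB) are either the synthetic
scene truth plus observation noise, or documented monotone proxy transforms
of the vegetation indices when no truth is available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from canopylink.scene import (
    BAND_NAMES,
    ENDMEMBER_NAMES,
    EndmemberLibrary,
    default_endmembers,
)

INDEX_NAMES = ("NDVI", "EVI", "SAVI", "RENDVI705", "NBRI", "GNDVI")


def _nd(a, b):
    """Normalized difference with NaN where the denominator vanishes."""
    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0, (a - b) / denom, np.nan)
    return out


def vegetation_indices(bands: pd.DataFrame, savi_l: float = 0.5) -> pd.DataFrame:
    """Six standard vegetation indices from the band table.

    NDVI = (B8-B4)/(B8+B4); EVI = 2.5(B8-B4)/(B8+6 B4-7.5 B2+1);
    SAVI = (B8-B4)/(B8+B4+L) (1+L); RENDVI705 = (B8-B5)/(B8+B5);
    NBRI = (B8-B12)/(B8+B12); GNDVI = (B8-B3)/(B8+B3).
    Cells with a vanishing denominator get NaN.
    """
    for b in ("B2", "B3", "B4", "B5", "B8", "B12"):
        if b not in bands.columns:
            raise ValueError(f"band table missing column {b!r}")
    b2 = bands["B2"].to_numpy(float)
    b3 = bands["B3"].to_numpy(float)
    b4 = bands["B4"].to_numpy(float)
    b5 = bands["B5"].to_numpy(float)
    b8 = bands["B8"].to_numpy(float)
    b12 = bands["B12"].to_numpy(float)
    evi_den = b8 + 6.0 * b4 - 7.5 * b2 + 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        evi = np.where(evi_den != 0, 2.5 * (b8 - b4) / evi_den, np.nan)
        savi_den = b8 + b4 + savi_l
        savi = np.where(savi_den != 0, (b8 - b4) / savi_den * (1.0 + savi_l), np.nan)
    out = pd.DataFrame(
        {
            "NDVI": _nd(b8, b4),
            "EVI": evi,
            "SAVI": savi,
            "RENDVI705": _nd(b8, b5),
            "NBRI": _nd(b8, b12),
            "GNDVI": _nd(b8, b3),
        }
    )
    if "cell_id" in bands.columns:
        out.insert(0, "cell_id", bands["cell_id"].to_numpy())
    return out


def unmix_fcls(
    spectra,
    endmembers: EndmemberLibrary | None = None,
    sum_to_one_weight: float = 1e3,
    max_condition: float = 1e8,
):
    """Fully constrained least-squares unmixing of one or many spectra.

    Solves min ||E f - s|| subject to f >= 0 and sum(f) = 1 via
    non-negative least squares on the sum-to-one-augmented system, then
    renormalizes exactly.  Returns ``(fractions, residual_norm)`` where
    fractions is an (n, 4) array in GV/NPV/Soil/Shade order.

    Raises for a degenerate (near-collinear) endmember library.
    """
    endmembers = endmembers or default_endmembers()
    E = endmembers.matrix()
    cond = np.linalg.cond(E)
    if not np.isfinite(cond) or cond > max_condition:
        raise ValueError(f"endmember library is near-collinear (condition {cond:.3g})")
    S = np.atleast_2d(np.asarray(spectra, dtype=float))
    if S.shape[1] != E.shape[0]:
        raise ValueError(
            f"spectra have {S.shape[1]} bands, library has {E.shape[0]}"
        )
    delta = sum_to_one_weight
    E_aug = np.vstack([E, delta * np.ones((1, E.shape[1]))])
    fracs = np.empty((S.shape[0], E.shape[1]))
    resid = np.empty(S.shape[0])
    for i, s in enumerate(S):
        s_aug = np.concatenate([s, [delta]])
        f, _ = nnls(E_aug, s_aug)
        total = f.sum()
        if total <= 0:  # all-zero solution: fall back to uniform
            f = np.full(E.shape[1], 1.0 / E.shape[1])
        else:
            f = f / total
        fracs[i] = f
        resid[i] = np.linalg.norm(E @ f - s)
    if np.ndim(spectra) == 1:
        return fracs[0], resid[0]
    return fracs, resid


def unmix_table(bands: pd.DataFrame, endmembers: EndmemberLibrary | None = None) -> pd.DataFrame:
    """FCLS fractions for every cell of a band table."""
    S = bands[list(BAND_NAMES)].to_numpy(float)
    fracs, resid = unmix_fcls(S, endmembers)
    out = pd.DataFrame(fracs, columns=list(ENDMEMBER_NAMES))
    out["unmix_residual"] = resid
    if "cell_id" in bands.columns:
        out.insert(0, "cell_id", bands["cell_id"].to_numpy())
    return out


def ndfi(fractions) -> np.ndarray | float:
    """Normalized difference fraction index from GV/NPV/Soil/Shade fractions.

    Accepts a DataFrame with those columns, a dict, or an (n, 4) array in
    that order.  Returns NaN where GV_shade and NPV+Soil are both zero.
    """
    if isinstance(fractions, pd.DataFrame):
        gv = fractions["GV"].to_numpy(float)
        npv = fractions["NPV"].to_numpy(float)
        soil = fractions["Soil"].to_numpy(float)
        shade = fractions["Shade"].to_numpy(float)
    elif isinstance(fractions, dict):
        gv, npv, soil, shade = (
            np.asarray(fractions[k], dtype=float) for k in ENDMEMBER_NAMES
        )
    else:
        arr = np.atleast_2d(np.asarray(fractions, dtype=float))
        gv, npv, soil, shade = arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]
    gv_shade = gv / (1.0 + shade)
    other = npv + soil
    denom = gv_shade + other
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, (gv_shade - other) / denom, np.nan)
    if out.size == 1 and np.ndim(fractions) in (0, 1) and not isinstance(fractions, pd.DataFrame):
        return float(out.ravel()[0])
    return out


def gv_shade(fractions) -> np.ndarray:
    """Shade-normalized green-vegetation fraction GV / (1 + Shade)."""
    if isinstance(fractions, pd.DataFrame):
        return fractions["GV"].to_numpy(float) / (1.0 + fractions["Shade"].to_numpy(float))
    arr = np.atleast_2d(np.asarray(fractions, dtype=float))
    return arr[:, 0] / (1.0 + arr[:, 3])


def biophysical_proxies(
    scene_truth: pd.DataFrame | None = None,
    indices: pd.DataFrame | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    extinction_k: float = 0.5,
) -> pd.DataFrame:
    """LAI / FAPAR / FCOVER / CAB per cell.

    Synthetic mode (``scene_truth`` given): the scene's true values plus
    Gaussian observation noise, clipped to valid ranges (LAI >= 0; FAPAR and
    FCOVER in [0, 1]).  Proxy mode (``indices`` given): documented monotone
    transforms of NDVI/GNDVI — approximations, flagged as such:

        LAI    = -ln(1 - clip(NDVI, 0, 0.98)) / k
        FCOVER = clip(NDVI, 0, 1)
        FAPAR  = 1 - exp(-k * LAI)
        CAB    = 15 + 45 * clip(GNDVI, 0, 1)
    """
    rng = np.random.default_rng(seed)
    if scene_truth is not None:
        lai = scene_truth["LAI"].to_numpy(float)
        fapar = scene_truth["FAPAR"].to_numpy(float)
        fcover = scene_truth["FCOVER"].to_numpy(float)
        cab = scene_truth["CAB"].to_numpy(float)
        cell = scene_truth.get("cell_id")
    elif indices is not None:
        ndvi = np.clip(indices["NDVI"].to_numpy(float), 0.0, 0.98)
        gndvi = np.clip(indices["GNDVI"].to_numpy(float), 0.0, 1.0)
        lai = -np.log(1.0 - ndvi) / extinction_k
        fcover = np.clip(indices["NDVI"].to_numpy(float), 0.0, 1.0)
        fapar = 1.0 - np.exp(-extinction_k * lai)
        cab = 15.0 + 45.0 * gndvi
        cell = indices.get("cell_id")
    else:
        raise ValueError("either scene_truth or indices must be provided")
    if noise_sd > 0:
        lai = lai + rng.normal(0, noise_sd, lai.shape)
        fapar = fapar + rng.normal(0, noise_sd, fapar.shape)
        fcover = fcover + rng.normal(0, noise_sd, fcover.shape)
        cab = cab + rng.normal(0, 10.0 * noise_sd, cab.shape)
    out = pd.DataFrame(
        {
            "LAI": np.maximum(lai, 0.0),
            "FAPAR": np.clip(fapar, 0.0, 1.0),
            "FCOVER": np.clip(fcover, 0.0, 1.0),
            "CAB": np.maximum(cab, 0.0),
        }
    )
    if cell is not None:
        out.insert(0, "cell_id", np.asarray(cell))
    return out


def spectral_feature_table(
    bands: pd.DataFrame,
    endmembers: EndmemberLibrary | None = None,
    scene_truth: pd.DataFrame | None = None,
    savi_l: float = 0.5,
    biophysical_noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """The full satellite feature set per cell.

    Columns: the 10 bands, 6 vegetation indices, 4 endmember fractions,
    GV_shade, NDFI, and the 4 biophysical variables — the candidate
    predictor pool for the satellite-phase regressions.
    """
    idx = vegetation_indices(bands, savi_l)
    fr = unmix_table(bands, endmembers)
    bio = biophysical_proxies(
        scene_truth=scene_truth,
        indices=idx if scene_truth is None else None,
        noise_sd=biophysical_noise_sd,
        seed=seed,
    )
    out = bands[["cell_id", *BAND_NAMES]].copy() if "cell_id" in bands.columns else bands[list(BAND_NAMES)].copy()
    for col in INDEX_NAMES:
        out[col] = idx[col].to_numpy()
    for col in ENDMEMBER_NAMES:
        out[col] = fr[col].to_numpy()
    out["GV_shade"] = gv_shade(fr)
    out["NDFI"] = ndfi(fr)
    for col in ("LAI", "FAPAR", "FCOVER", "CAB"):
        out[col] = bio[col].to_numpy()
    return out
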