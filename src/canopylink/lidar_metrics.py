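"""Canopy height metrics per 20 m grid cell from normalized point clouds.

The metric set is the standard area-based inventory family: height
percentiles of first returns, canopy return density in equal-height slices,
moment statistics, and cover metrics (canopy cover above 2 m, gap fraction,
canopy relief ratio, a Beer-Lambert leaf area index).

Per-metric return filters:

* percentiles, ``Hmean`` and ``CC`` use first returns,
* the moment metrics (``Hvar``, ``Hstd``, ``Hskew``, ``Hkurtosis``,
  ``Hmd``), ``GF`` and ``CRR`` use all returns,
* ``Hmax`` is the maximum over returns above the 2 m canopy threshold
  (0 when no return exceeds it),
* ``Hcv`` = ``Hstd`` / ``Hmean``.

All filters are overridable through :class:`MetricConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from canopylink.grid import GridFramework
from canopylink.pointcloud import PointCloud

PERCENTILE_LEVELS = (1, 5, 10, 20, 25, 30, 40, 50, 60, 70, 75, 80, 90, 95, 99)

#: Metric column names, in report order.
CANOPY_METRIC_NAMES = tuple(
    [f"H{p}" for p in PERCENTILE_LEVELS]
    + [f"D{i}" for i in range(1, 10)]
    + ["Hvar", "Hmax", "Hcv", "Hskew", "Hmd", "Hkurtosis", "Hstd", "Hmean",
       "CRR", "CC", "GF", "LAI"]
)


@dataclass(frozen=True)
class MetricConfig:
    canopy_threshold: float = 2.0  # m; CC / GF / Hmax height threshold
    extinction_k: float = 0.5      # Beer-Lambert extinction coefficient
    min_points: int = 10           # minimum returns for a valid cell
    hmax_above_threshold: bool = True  # point filter on Hmax (configurable)


def height_percentiles(heights, levels=PERCENTILE_LEVELS) -> dict:
    """Linear-interpolation percentiles of first-return heights."""
    h = np.asarray(heights, dtype=float)
    if h.size == 0:
        return {f"H{p}": np.nan for p in levels}
    vals = np.percentile(h, levels, method="linear")
    return {f"H{p}": v for p, v in zip(levels, vals)}


def density_metrics(heights) -> dict:
    """D1..D9: proportion of returns above each of 9 equal-height slice
    boundaries of [min, max]; all zero when the range is degenerate."""
    h = np.asarray(heights, dtype=float)
    out = {}
    if h.size == 0:
        return {f"D{i}": np.nan for i in range(1, 10)}
    lo, hi = h.min(), h.max()
    if hi - lo <= 0:
        return {f"D{i}": 0.0 for i in range(1, 10)}
    for i in range(1, 10):
        boundary = lo + (hi - lo) * i / 10.0
        out[f"D{i}"] = float((h > boundary).mean())
    return out


def moment_metrics(heights) -> dict:
    """Moment statistics of all-return heights.

    Sample SD (n-1 denominator); skewness and kurtosis are the standard
    moment definitions (kurtosis non-excess, so a normal sample gives ~3);
    ``Hmd`` is the median absolute deviation about the median.
    """
    h = np.asarray(heights, dtype=float)
    n = h.size
    if n == 0:
        return {k: np.nan for k in ("Hmean_all", "Hvar", "Hstd", "Hskew", "Hkurtosis", "Hmd")}
    mean = h.mean()
    if n > 1:
        var = h.var(ddof=1)
    else:
        var = 0.0
    std = np.sqrt(var)
    dev = h - mean
    m2 = (dev**2).mean()
    if m2 > 0:
        skew = (dev**3).mean() / m2**1.5
        kurt = (dev**4).mean() / m2**2
    else:
        skew = 0.0
        kurt = 0.0
    med = np.median(h)
    hmd = np.median(np.abs(h - med))
    return {
        "Hmean_all": mean, "Hvar": var, "Hstd": std,
        "Hskew": skew, "Hkurtosis": kurt, "Hmd": hmd,
    }


def cover_metrics(first_heights, all_heights, config: MetricConfig = MetricConfig()) -> dict:
    """CC, GF, CRR, LAI and Hmax for one cell.

    ``CC`` = share of first returns above the canopy threshold; ``GF`` =
    share of all returns at or below it (floored at 1/(n+1) inside the LAI
    logarithm); ``CRR`` = (mean - min)/(max - min) of all returns; ``LAI`` =
    -ln(GF)/k.
    """
    hf = np.asarray(first_heights, dtype=float)
    ha = np.asarray(all_heights, dtype=float)
    t = config.canopy_threshold
    cc = float((hf > t).mean()) if hf.size else np.nan
    gf = float((ha <= t).mean()) if ha.size else np.nan
    if ha.size:
        rng = ha.max() - ha.min()
        crr = float((ha.mean() - ha.min()) / rng) if rng > 0 else 0.0
        above = ha[ha > t]
        if config.hmax_above_threshold:
            hmax = float(above.max()) if above.size else 0.0
        else:
            hmax = float(ha.max())
        gf_floored = max(gf, 1.0 / (ha.size + 1))
        lai = -np.log(gf_floored) / config.extinction_k
    else:
        crr = hmax = lai = np.nan
    return {"CC": cc, "GF": gf, "CRR": crr, "LAI": lai, "Hmax": hmax}


def cell_metrics(first_heights, all_heights, config: MetricConfig = MetricConfig()) -> dict:
    """All metrics for one cell from its first-return and all-return heights."""
    out = {}
    out.update(height_percentiles(first_heights))
    out.update(density_metrics(all_heights))
    moments = moment_metrics(all_heights)
    out.update({k: v for k, v in moments.items() if k != "Hmean_all"})
    hf = np.asarray(first_heights, dtype=float)
    hmean = hf.mean() if hf.size else np.nan
    out["Hmean"] = hmean
    out["Hcv"] = out["Hstd"] / hmean if hf.size and hmean > 0 else np.nan
    out.update(cover_metrics(first_heights, all_heights, config))
    return out


def extract_cell_metrics(
    cloud: PointCloud,
    grid: GridFramework,
    config: MetricConfig = MetricConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell metric table from a normalized cloud.

    Returns ``(features, underpopulated)``: one row per valid cell with
    columns cell_id, x_center, y_center, n_points and the metric set;
    cells with fewer than ``config.min_points`` returns are listed in the
    second frame (cell_id, n_points) and excluded from the first.
    """
    if not cloud.is_normalized:
        raise ValueError(
            "cloud has no normalized heights; run the preprocessing chain first"
        )
    work = cloud.without_noise()
    ids = grid.point_to_cell(work.x, work.y)
    ok = ids >= 0
    if not ok.any():
        import warnings

        warnings.warn("no points intersect the grid framework")
        return (
            pd.DataFrame(columns=["cell_id", "x_center", "y_center", "n_points", *CANOPY_METRIC_NAMES]),
            pd.DataFrame(columns=["cell_id", "n_points"]),
        )
    df = pd.DataFrame(
        {
            "cell_id": ids[ok],
            "h": work.height[ok],
            "first": work.return_number[ok] == 1,
        }
    )
    rows = []
    under = []
    for cid, g in df.groupby("cell_id", sort=True):
        n = len(g)
        if n < config.min_points:
            under.append((cid, n))
            continue
        m = cell_metrics(g.loc[g["first"], "h"].to_numpy(), g["h"].to_numpy(), config)
        x, y = grid.cell_center(cid)
        rows.append({"cell_id": cid, "x_center": float(x), "y_center": float(y),
                     "n_points": n, **m})
    features = pd.DataFrame(rows, columns=["cell_id", "x_center", "y_center",
                                           "n_points", *CANOPY_METRIC_NAMES])
    underpopulated = pd.DataFrame(under, columns=["cell_id", "n_points"])
    return features, underpopulated
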