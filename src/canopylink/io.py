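"""Readers and writers for the pipeline's plain-text artifacts.

Point clouds travel as XYZ-CSV (columns ``x,y,z,return_number`` plus
optional ``classification``, ``truth_class``, ``height``); band stacks and
feature tables as CSV keyed by ``cell_id``; the grid framework as YAML; the
final AGB map as a float32 TIFF with an ESRI world file (.tfw) and a CSV
twin.  Every intermediate artifact is a standard format, so any stage can
be re-run from its inputs alone.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from canopylink.grid import GridFramework
from canopylink.pointcloud import PointCloud
from canopylink.scene import BAND_NAMES

POINT_COLUMNS = ("x", "y", "z", "return_number")
OPTIONAL_POINT_COLUMNS = ("classification", "truth_class", "height")


# ---------------------------------------------------------------------------
# point clouds
# ---------------------------------------------------------------------------


def write_point_cloud(cloud: PointCloud, path) -> None:
    path = Path(path)
    if path.suffix.lower() != ".csv":
        raise ValueError(
            f"unsupported point-cloud format {path.suffix!r}; use XYZ-CSV (.csv)"
        )
    data = {
        "x": cloud.x, "y": cloud.y, "z": cloud.z,
        "return_number": cloud.return_number,
        "classification": cloud.classification,
    }
    if cloud.truth_class is not None:
        data["truth_class"] = cloud.truth_class
    if cloud.height is not None:
        data["height"] = cloud.height
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.4f")


def read_point_cloud(path) -> PointCloud:
    path = Path(path)
    if path.suffix.lower() != ".csv":
        raise ValueError(
            f"unsupported point-cloud format {path.suffix!r}; use XYZ-CSV (.csv)"
        )
    df = pd.read_csv(path)
    missing = [c for c in POINT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"point-cloud CSV {path} missing columns {missing}")
    return PointCloud(
        df["x"].to_numpy(float),
        df["y"].to_numpy(float),
        df["z"].to_numpy(float),
        df["return_number"].to_numpy(),
        df["classification"].to_numpy() if "classification" in df.columns else None,
        df["truth_class"].to_numpy(object) if "truth_class" in df.columns else None,
        df["height"].to_numpy(float) if "height" in df.columns else None,
    )


# ---------------------------------------------------------------------------
# band stacks
# ---------------------------------------------------------------------------


def read_band_stack(path, grid: GridFramework | None = None) -> pd.DataFrame:
    """Read a per-cell band table, or resample a pixel table to the grid.

    Two CSV layouts are accepted:

    * ``cell_id,B2,...,B12`` — already on the framework; returned unchanged
      (after band validation),
    * ``x,y,B2,...,B12`` — pixel centres at any resolution; each grid cell
      takes the value of the pixel centre nearest its own centre
      (nearest-neighbour resampling; requires ``grid``).
    """
    df = pd.read_csv(path)
    missing = [b for b in BAND_NAMES if b not in df.columns]
    if missing:
        raise ValueError(f"band stack {path} missing bands {missing}")
    if "cell_id" in df.columns:
        return df[["cell_id", *BAND_NAMES]]
    if not {"x", "y"}.issubset(df.columns):
        raise ValueError(f"band stack {path} needs either cell_id or x,y columns")
    if grid is None:
        raise ValueError("a grid framework is required to resample a pixel table")
    from scipy.spatial import cKDTree

    kd = cKDTree(df[["x", "y"]].to_numpy(float))
    ids = grid.all_cell_ids()
    cx, cy = grid.cell_center(ids)
    _, nearest = kd.query(np.column_stack([cx, cy]))
    out = df.iloc[nearest][list(BAND_NAMES)].reset_index(drop=True)
    out.insert(0, "cell_id", ids)
    return out


# ---------------------------------------------------------------------------
# grid framework
# ---------------------------------------------------------------------------


def write_grid(grid: GridFramework, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(
            {
                "origin_x": grid.origin_x, "origin_y": grid.origin_y,
                "cell_size": grid.cell_size, "n_rows": grid.n_rows,
                "n_cols": grid.n_cols, "crs": grid.crs,
            },
            sort_keys=False,
        )
    )


def read_grid(path) -> GridFramework:
    d = yaml.safe_load(Path(path).read_text())
    return GridFramework(**d)


# ---------------------------------------------------------------------------
# AGB map
# ---------------------------------------------------------------------------


def write_agb_map(agb_map: np.ndarray, grid: GridFramework, path) -> None:
    """Write the 20 m AGB raster as float32 TIFF + ESRI world file + CSV.

    The world file carries the affine georeferencing (cell size, centre of
    the upper-left cell); nodata is -9999.
    """
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, np.asarray(agb_map, dtype=np.float32))
    cs = grid.cell_size
    _, _, _, ymax = grid.extent
    world = "\n".join(
        str(v)
        for v in (cs, 0.0, 0.0, -cs, grid.origin_x + cs / 2, ymax - cs / 2)
    )
    path.with_suffix(".tfw").write_text(world + "\n")
    ids = grid.all_cell_ids()
    rows, cols = grid.cell_rowcol(ids)
    x, y = grid.cell_center(ids)
    pd.DataFrame(
        {"cell_id": ids, "x_center": x, "y_center": y,
         "agb_mgha": np.asarray(agb_map)[rows, cols]}
    ).to_csv(path.with_suffix(".csv"), index=False, float_format="%.3f")


def read_agb_map(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)


# ---------------------------------------------------------------------------
# run outputs
# ---------------------------------------------------------------------------


def write_run_outputs(result: dict, grid: GridFramework, out_dir) -> None:
    """Write the standard artifact set of a full pipeline run."""
    from canopylink.twophase import report_frame

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report_frame(result["reports"]).to_csv(
        out / "report_table5.csv", index=False, float_format="%.4f"
    )
    report_frame(result["truth_reports"]).to_csv(
        out / "report_vs_truth.csv", index=False, float_format="%.4f"
    )
    for key, name in (
        ("phase1", "selection_phase1.csv"),
        ("phase2", "selection_phase2.csv"),
        ("direct", "selection_direct.csv"),
    ):
        result[key].selection.to_frame().to_csv(out / name, index=False, float_format="%.6f")
    write_agb_map(result["agb_map"], grid, out / "agb_map.tif")
    result["lidar_features"].to_csv(
        out / "lidar_features.csv", index=False, float_format="%.6f"
    )
    result["sat_features"].to_csv(
        out / "satellite_features.csv", index=False, float_format="%.6f"
    )
    result["reference"].to_frame().to_csv(
        out / "reference_cells.csv", index=False, float_format="%.4f"
    )
    scene = result.get("scene")
    if scene is not None:
        scene.plots.to_csv(out / "plots.csv", index=False, float_format="%.4f")
        scene.blocks.to_csv(out / "blocks.csv", index=False, float_format="%.2f")
        write_grid(grid, out / "grid.yaml")
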