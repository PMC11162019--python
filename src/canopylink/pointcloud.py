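"""Point-cloud preprocessing: denoise, ground filter, DTM, normalization.

The chain mirrors a standard area-based lidar workflow:

1. :func:`remove_outliers` — statistical outlier removal on mean k-NN
   distance,
2. :func:`classify_ground_ptd` — progressive TIN densification (seed the
   lowest point per coarse cell, then iteratively accept points close and
   flat-angled to the current triangulation),
3. :func:`build_dtm_idw` — inverse-distance-weighted ground raster,
4. :func:`normalize_heights` — per-point height above the DTM (bilinear
   lookup), with a small negative tolerance clamped to zero.

Downstream metric extraction refuses clouds that have not been normalized,
so the order of the chain is enforced by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import Delaunay, cKDTree

# LAS-style classification codes
CLASS_UNCLASSIFIED = 0
CLASS_NON_GROUND = 1
CLASS_GROUND = 2
CLASS_NOISE = 7


@dataclass
class PointCloud:
    """Georeferenced lidar returns.

    ``height`` (normalized height above ground, m) exists only after
    :func:`normalize_heights`; ``truth_class`` is the synthetic generator's
    ground/canopy label and is absent on real data.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    return_number: np.ndarray
    classification: np.ndarray = None
    truth_class: np.ndarray = None
    height: np.ndarray = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.return_number = np.asarray(self.return_number, dtype=np.int16)
        if self.classification is None:
            self.classification = np.full(self.x.size, CLASS_UNCLASSIFIED, np.uint8)
        else:
            self.classification = np.asarray(self.classification, dtype=np.uint8)
        lengths = {
            self.x.size, self.y.size, self.z.size,
            self.return_number.size, self.classification.size,
        }
        if self.truth_class is not None:
            self.truth_class = np.asarray(self.truth_class, dtype=object)
            lengths.add(self.truth_class.size)
        if self.height is not None:
            self.height = np.asarray(self.height, dtype=float)
            lengths.add(self.height.size)
        if len(lengths) != 1:
            raise ValueError("point cloud arrays must have equal length")

    def __len__(self) -> int:
        return self.x.size

    @property
    def is_normalized(self) -> bool:
        return self.height is not None

    def mask(self, keep: np.ndarray) -> "PointCloud":
        """A new cloud restricted to ``keep`` (boolean or index array)."""
        return PointCloud(
            self.x[keep], self.y[keep], self.z[keep], self.return_number[keep],
            self.classification[keep],
            None if self.truth_class is None else self.truth_class[keep],
            None if self.height is None else self.height[keep],
        )

    def without_noise(self) -> "PointCloud":
        return self.mask(self.classification != CLASS_NOISE)

    @staticmethod
    def concatenate(parts: list["PointCloud"]) -> "PointCloud":
        has_truth = all(p.truth_class is not None for p in parts)
        has_h = all(p.height is not None for p in parts)
        return PointCloud(
            np.concatenate([p.x for p in parts]),
            np.concatenate([p.y for p in parts]),
            np.concatenate([p.z for p in parts]),
            np.concatenate([p.return_number for p in parts]),
            np.concatenate([p.classification for p in parts]),
            np.concatenate([p.truth_class for p in parts]) if has_truth else None,
            np.concatenate([p.height for p in parts]) if has_h else None,
        )


@dataclass
class Dtm:
    """Ground-elevation raster (row 0 at the north edge, NaN = nodata)."""

    origin_x: float
    origin_y: float  # y of the SOUTH-WEST corner
    resolution: float
    values: np.ndarray  # (n_rows, n_cols), row 0 northernmost

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def node_coords(self):
        """x of columns and y of rows (node centres), y descending row-wise."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.resolution
        ys = self.origin_y + (self.n_rows - np.arange(self.n_rows) - 0.5) * self.resolution
        return xs, ys

    def sample_bilinear(self, x, y):
        """Bilinear DTM elevation at arbitrary points (NaN outside/nodata)."""
        xs, ys = self.node_coords()
        interp = RegularGridInterpolator(
            (ys[::-1], xs), self.values[::-1, :],
            method="linear", bounds_error=False, fill_value=np.nan,
        )
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        # clamp half-a-node so points between the edge node and raster border
        # use edge values rather than dropping out
        xq = np.clip(x, xs[0], xs[-1])
        yq = np.clip(y, ys[-1], ys[0])
        return interp(np.column_stack([np.ravel(yq), np.ravel(xq)])).reshape(x.shape)


# ---------------------------------------------------------------------------
# 1. statistical outlier removal
# ---------------------------------------------------------------------------


def remove_outliers(cloud: PointCloud, k_neighbors: int = 10, sd_multiplier: float = 3.0) -> PointCloud:
    """Label isolated returns as noise (statistical outlier removal).

    A point is noise when its mean distance to its ``k_neighbors`` nearest
    neighbours exceeds the global mean of that quantity by more than
    ``sd_multiplier`` standard deviations.  Other labels are untouched.
    """
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    if sd_multiplier <= 0:
        raise ValueError("sd_multiplier must be positive")
    n = len(cloud)
    if n <= k_neighbors:
        warnings.warn("cloud smaller than k+1 points; outlier removal skipped")
        return cloud
    pts = np.column_stack([cloud.x, cloud.y, cloud.z])
    kd = cKDTree(pts)
    dist, _ = kd.query(pts, k=k_neighbors + 1, workers=-1)
    mean_knn = dist[:, 1:].mean(axis=1)
    thresh = mean_knn.mean() + sd_multiplier * mean_knn.std()
    out = cloud.mask(np.ones(n, bool))  # copy
    out.classification = out.classification.copy()
    out.classification[mean_knn > thresh] = CLASS_NOISE
    return out


# ---------------------------------------------------------------------------
# 2. progressive TIN densification ground filter
# ---------------------------------------------------------------------------


def _facet_geometry(tri: Delaunay, simplex: np.ndarray, pts_xy: np.ndarray,
                    pts_z: np.ndarray, zv: np.ndarray):
    """Vertical distance to facet plane and max angle to facet vertices."""
    verts = tri.simplices[simplex]  # (m, 3) indices into triangulation points
    p = tri.points[verts]  # (m, 3, 2)
    z = zv[verts]  # (m, 3)
    # plane z = a*x + b*y + c through the 3 vertices
    v1 = np.column_stack([p[:, 1] - p[:, 0], z[:, 1] - z[:, 0]])
    v2 = np.column_stack([p[:, 2] - p[:, 0], z[:, 2] - z[:, 0]])
    nrm = np.cross(v1, v2)
    nz = nrm[:, 2]
    nz = np.where(np.abs(nz) < 1e-12, 1e-12, nz)
    z_on_plane = z[:, 0] - (
        nrm[:, 0] * (pts_xy[:, 0] - p[:, 0, 0]) + nrm[:, 1] * (pts_xy[:, 1] - p[:, 0, 1])
    ) / nz
    dz = pts_z - z_on_plane
    dist = np.abs(dz)
    # angle between the facet plane and the segment point -> each vertex
    seg = np.sqrt(
        (pts_xy[:, None, 0] - p[:, :, 0]) ** 2
        + (pts_xy[:, None, 1] - p[:, :, 1]) ** 2
        + (pts_z[:, None] - z) ** 2
    )
    seg = np.maximum(seg, 1e-12)
    ratio = np.clip(dist[:, None] / seg, 0.0, 1.0)
    angle = np.degrees(np.arcsin(ratio)).max(axis=1)
    return dist, angle, dz


def classify_ground_ptd(
    cloud: PointCloud,
    seed_cell_size: float = 20.0,
    max_angle_deg: float = 8.0,
    max_distance: float = 0.5,
    max_iterations: int = 30,
) -> PointCloud:
    """Progressive TIN densification (PTD) ground classification.

    Seeds are the lowest point per ``seed_cell_size`` cell (ties broken by
    lowest point index).  A Delaunay TIN is built over the seeds and points
    are iteratively accepted as ground when their vertical distance to the
    containing facet is below ``max_distance`` and the maximum angle between
    the facet plane and the segments to its vertices is below
    ``max_angle_deg``; iteration continues to a fixpoint.  Deterministic.
    """
    work = cloud.without_noise()
    if len(work) < 3:
        raise ValueError("fewer than 3 non-noise points; cannot build TIN")

    # --- seed points: lowest per coarse cell
    cx = np.floor((work.x - work.x.min()) / seed_cell_size).astype(np.int64)
    cy = np.floor((work.y - work.y.min()) / seed_cell_size).astype(np.int64)
    key = cx * (cy.max() + 1) + cy
    order = np.lexsort((np.arange(len(work)), work.z, key))
    ordered_keys = key[order]
    first = np.ones(len(work), bool)
    first[1:] = ordered_keys[1:] != ordered_keys[:-1]
    seed_idx = order[first]
    if seed_idx.size < 3:
        raise ValueError(
            f"only {seed_idx.size} seed cells; need >= 3 for a triangulation"
        )

    is_ground = np.zeros(len(work), bool)
    is_ground[seed_idx] = True

    pts_xy = np.column_stack([work.x, work.y])
    z = work.z

    # virtual corner vertices keep the TIN covering the whole footprint
    # (border points would otherwise fall outside the convex hull of the
    # seeds and could never be classified); each carries the elevation of
    # its nearest seed.
    pad = 1.0
    corners = np.array(
        [
            (work.x.min() - pad, work.y.min() - pad),
            (work.x.min() - pad, work.y.max() + pad),
            (work.x.max() + pad, work.y.min() - pad),
            (work.x.max() + pad, work.y.max() + pad),
        ]
    )
    seed_kd = cKDTree(pts_xy[seed_idx])
    _, nearest_seed = seed_kd.query(corners)
    corner_z = z[seed_idx][nearest_seed]

    for _ in range(max_iterations):
        g_idx = np.flatnonzero(is_ground)
        if g_idx.size < 3:
            break
        tri_xy = np.vstack([pts_xy[g_idx], corners])
        tri_z = np.concatenate([z[g_idx], corner_z])
        try:
            tri = Delaunay(tri_xy)
        except Exception:  # degenerate (collinear) seed geometry
            break
        cand = np.flatnonzero(~is_ground)
        if cand.size == 0:
            break
        simplex = tri.find_simplex(pts_xy[cand])
        inside = simplex >= 0
        if not inside.any():
            break
        ci = cand[inside]
        dist, angle, dz = _facet_geometry(
            tri, simplex[inside], pts_xy[ci], z[ci], tri_z
        )
        accept = (dist <= max_distance) & (angle <= max_angle_deg)
        if not accept.any():
            break
        is_ground[ci[accept]] = True

    # write labels back onto the full cloud (noise keeps its label)
    out = cloud.mask(np.ones(len(cloud), bool))
    out.classification = out.classification.copy()
    not_noise = out.classification != CLASS_NOISE
    labels = np.where(is_ground, CLASS_GROUND, CLASS_NON_GROUND).astype(np.uint8)
    out.classification[not_noise] = labels
    return out


# ---------------------------------------------------------------------------
# 3. IDW DTM
# ---------------------------------------------------------------------------


def build_dtm_idw(
    ground: PointCloud | tuple,
    resolution: float = 1.0,
    power: float = 2.0,
    n_neighbors: int = 12,
    max_radius: float = 50.0,
) -> Dtm:
    """Inverse-distance-weighted ground raster from ground-labelled points.

    A node coincident with a ground point takes that point's elevation
    exactly; nodes farther than ``max_radius`` from every ground point are
    nodata (NaN).
    """
    if isinstance(ground, PointCloud):
        sel = ground.classification == CLASS_GROUND
        gx, gy, gz = ground.x[sel], ground.y[sel], ground.z[sel]
    else:
        gx, gy, gz = (np.asarray(a, dtype=float) for a in ground)
    if gx.size == 0:
        raise ValueError("no ground points; cannot interpolate a DTM")

    x0 = np.floor(gx.min() / resolution) * resolution
    y0 = np.floor(gy.min() / resolution) * resolution
    n_cols = max(int(np.ceil((gx.max() - x0) / resolution)), 1)
    n_rows = max(int(np.ceil((gy.max() - y0) / resolution)), 1)

    xs = x0 + (np.arange(n_cols) + 0.5) * resolution
    ys = y0 + (n_rows - np.arange(n_rows) - 0.5) * resolution
    gxq, gyq = np.meshgrid(xs, ys)
    nodes = np.column_stack([gxq.ravel(), gyq.ravel()])

    kd = cKDTree(np.column_stack([gx, gy]))
    k = min(n_neighbors, gx.size)
    dist, idx = kd.query(nodes, k=k, workers=-1)
    if k == 1:
        dist = dist[:, None]
        idx = idx[:, None]

    with np.errstate(divide="ignore"):
        w = 1.0 / dist**power
    exact = dist[:, 0] < 1e-9
    vals = np.empty(nodes.shape[0])
    vals[exact] = gz[idx[exact, 0]]
    ne = ~exact
    zn = gz[idx[ne]]
    wn = w[ne]
    vals[ne] = (wn * zn).sum(axis=1) / wn.sum(axis=1)
    vals[dist[:, 0] > max_radius] = np.nan

    return Dtm(x0, y0, float(resolution), vals.reshape(n_rows, n_cols))


# ---------------------------------------------------------------------------
# 4. height normalization
# ---------------------------------------------------------------------------


def normalize_heights(
    cloud: PointCloud, dtm: Dtm, clamp_floor: float = -0.2
) -> tuple[PointCloud, int]:
    """Per-point height above ground via bilinear DTM lookup.

    Negative heights are clamped to zero; heights below ``clamp_floor`` are
    treated the same but counted (they usually indicate DTM error).  Points
    outside the DTM coverage are excluded; the count of excluded points is
    returned alongside the normalized cloud.
    """
    ground_z = dtm.sample_bilinear(cloud.x, cloud.y)
    covered = np.isfinite(ground_z)
    n_excluded = int((~covered).sum())
    out = cloud.mask(covered)
    h = out.z - ground_z[covered]
    below_floor = int((h < clamp_floor).sum())
    if below_floor:
        warnings.warn(
            f"{below_floor} points more than {-clamp_floor} m below the DTM; clamped"
        )
    out.height = np.maximum(h, 0.0)
    return out, n_excluded


def preprocess(
    cloud: PointCloud,
    k_neighbors: int = 10,
    sd_multiplier: float = 3.0,
    seed_cell_size: float = 20.0,
    max_angle_deg: float = 8.0,
    max_distance: float = 0.5,
    dtm_resolution: float = 1.0,
    idw_power: float = 2.0,
    idw_neighbors: int = 12,
) -> tuple[PointCloud, Dtm]:
    """Full chain: denoise -> PTD ground filter -> IDW DTM -> normalize."""
    c = remove_outliers(cloud, k_neighbors, sd_multiplier)
    c = classify_ground_ptd(c, seed_cell_size, max_angle_deg, max_distance)
    dtm = build_dtm_idw(c, dtm_resolution, idw_power, idw_neighbors)
    normed, _ = normalize_heights(c, dtm)
    return normed, dtm


def normalize_against_terrain(cloud: PointCloud, terrain) -> PointCloud:
    """Normalize heights against a known terrain surface (synthetic mode).

    Used when the study question is downstream of preprocessing and the
    scene's true terrain is available; the full chain is exercised by
    :func:`preprocess`.
    """
    out = cloud.without_noise()
    out.height = np.maximum(out.z - terrain.elevation(out.x, out.y), 0.0)
    return out
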