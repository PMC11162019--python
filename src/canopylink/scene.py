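"""Seeded synthetic forest scenes for an open-woodland biomass study.

The generator produces every input the two-phase pipeline consumes:

* a smooth random terrain surface,
* a tree list (stem positions, DBH, height, species, crown radius, biomass)
  from an inhomogeneous Poisson process with a truncated-Weibull diameter
  distribution and a monotone hypsometric curve,
* a discrete-return lidar point cloud over the flight blocks (crown
  envelopes are vertical-axis spheroids; pulses either hit the highest
  covering crown or reach the ground, with a penetration probability
  producing second returns),
* per-cell truth (AGB, canopy cover, endmember fractions, biophysical
  variables) and linearly mixed multispectral reflectance,
* a block/plot layout mirroring a field campaign: rectangular flight
  blocks, circular 10 m-radius plots centred on grid-cell centres with a
  minimum spacing and a border buffer.

Everything is deterministic for a fixed configuration and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree
from shapely.geometry import box

from canopylink.grid import GridFramework, make_fishnet
from canopylink.pointcloud import PointCloud, CLASS_UNCLASSIFIED

MIN_DBH_CM = 5.0

SPECIES_POOL = (
    "Brachystegia spiciformis",
    "Brachystegia longifolia",
    "Julbernardia globiflora",
    "Julbernardia paniculata",
    "Isoberlinia angolensis",
    "Pterocarpus angolensis",
)
SPECIES_WEIGHTS = (0.28, 0.20, 0.20, 0.14, 0.12, 0.06)

#: Band names of the 20 m multispectral stack (blue .. shortwave infrared).
BAND_NAMES = ("B2", "B3", "B4", "B5", "B6", "B7", "B8", "B8A", "B11", "B12")

ENDMEMBER_NAMES = ("GV", "NPV", "Soil", "Shade")


@dataclass(frozen=True)
class EndmemberLibrary:
    """Pure-material reflectance spectra over the 10 bands (unitless 0-1)."""

    spectra: dict  # name -> tuple of reflectances, one per band

    def __post_init__(self):
        for name in ENDMEMBER_NAMES:
            if name not in self.spectra:
                raise ValueError(f"endmember library missing {name!r}")
        for name, spec in self.spectra.items():
            arr = np.asarray(spec, dtype=float)
            if arr.shape != (len(BAND_NAMES),):
                raise ValueError(
                    f"endmember {name!r} must have {len(BAND_NAMES)} bands"
                )
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"endmember {name!r} reflectance outside [0,1]")

    def matrix(self, names=ENDMEMBER_NAMES) -> np.ndarray:
        """Bands x endmembers matrix in the given endmember order."""
        return np.column_stack([np.asarray(self.spectra[n], float) for n in names])


def default_endmembers() -> EndmemberLibrary:
    """A generic green-vegetation / dry-vegetation / soil / shade library.

    GV: strong red-edge ramp and high NIR; NPV: bright SWIR with a dry-matter
    plateau; Soil: monotone brightening toward SWIR; Shade: near-dark flat.
    """
    return EndmemberLibrary(
        {
            "GV": (0.02, 0.05, 0.03, 0.12, 0.30, 0.38, 0.42, 0.44, 0.22, 0.10),
            "NPV": (0.07, 0.10, 0.16, 0.22, 0.27, 0.30, 0.33, 0.34, 0.45, 0.28),
            "Soil": (0.12, 0.16, 0.22, 0.26, 0.28, 0.30, 0.32, 0.33, 0.38, 0.36),
            "Shade": (0.01, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01, 0.005, 0.005),
        }
    )


# ---------------------------------------------------------------------------
# terrain
# ---------------------------------------------------------------------------


@dataclass
class TerrainModel:
    """A smooth band-limited elevation surface over a rectangular extent."""

    extent: tuple  # (xmin, ymin, xmax, ymax)
    relief_amplitude: float
    correlation_length: float
    seed: int
    base_elevation: float = 1200.0
    _grid_res: float = 5.0
    _xs: np.ndarray = field(default=None, repr=False)
    _ys: np.ndarray = field(default=None, repr=False)
    _z: np.ndarray = field(default=None, repr=False)
    _interp: RegularGridInterpolator = field(default=None, repr=False)

    def elevation(self, x, y):
        """Ground elevation (m above datum) at arbitrary coordinates."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self._interp is None:
            return np.broadcast_to(
                np.float64(self.base_elevation), np.broadcast_shapes(x.shape, y.shape)
            ).copy()
        xmin, ymin, xmax, ymax = self.extent
        xq = np.clip(x, xmin, xmax)
        yq = np.clip(y, ymin, ymax)
        pts = np.column_stack([np.ravel(yq), np.ravel(xq)])
        out = self._interp(pts)
        return out.reshape(np.broadcast_shapes(x.shape, y.shape))


def generate_terrain(
    extent,
    relief_amplitude: float = 8.0,
    correlation_length: float = 200.0,
    seed: int = 0,
    base_elevation: float = 1200.0,
) -> TerrainModel:
    """Smooth correlated terrain: filtered white noise scaled to amplitude.

    The surface is white noise smoothed with a Gaussian kernel of standard
    deviation ``correlation_length`` and rescaled so that the absolute
    deviation from the base elevation never exceeds ``relief_amplitude``
    (hence max - min <= 2 * amplitude).  Amplitude 0 gives a constant plane.
    """
    xmin, ymin, xmax, ymax = map(float, extent)
    if xmax <= xmin or ymax <= ymin:
        raise ValueError(f"extent must have positive area, got {extent}")
    if relief_amplitude < 0:
        raise ValueError("relief_amplitude must be >= 0")
    model = TerrainModel(
        extent=(xmin, ymin, xmax, ymax),
        relief_amplitude=float(relief_amplitude),
        correlation_length=float(correlation_length),
        seed=int(seed),
        base_elevation=float(base_elevation),
    )
    if relief_amplitude == 0:
        return model
    res = model._grid_res
    nx = max(int(np.ceil((xmax - xmin) / res)) + 1, 4)
    ny = max(int(np.ceil((ymax - ymin) / res)) + 1, 4)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((ny, nx))
    sigma = max(correlation_length / res, 1.0)
    smooth = ndimage.gaussian_filter(noise, sigma=sigma, mode="mirror")
    peak = np.max(np.abs(smooth))
    if peak > 0:
        smooth = smooth / peak
    z = model.base_elevation + relief_amplitude * smooth
    xs = np.linspace(xmin, xmax, nx)
    ys = np.linspace(ymin, ymax, ny)
    model._xs, model._ys, model._z = xs, ys, z
    model._interp = RegularGridInterpolator(
        (ys, xs), z, method="linear", bounds_error=False, fill_value=None
    )
    return model


# ---------------------------------------------------------------------------
# trees and allometry
# ---------------------------------------------------------------------------


def allometric_agb(dbh, height, coeff_a: float = 0.0613, coeff_b: float = 0.976):
    """Tree above-ground biomass (kg) from a power law a * (dbh^2 * h)^b.

    ``dbh`` in cm, ``height`` in m.  The pan-tropical form AGB = a(D^2 H)^b
    is the standard shape for dry-woodland allometries; the coefficients are
    configurable because site-specific values vary by region and species.
    """
    dbh = np.asarray(dbh, dtype=float)
    height = np.asarray(height, dtype=float)
    if coeff_a <= 0:
        raise ValueError("coeff_a must be positive")
    if np.any(dbh <= 0) or np.any(height <= 0):
        raise ValueError("dbh and height must be positive")
    return coeff_a * (dbh**2 * height) ** coeff_b


def _sample_truncated_weibull(rng, n, shape, scale, minimum):
    """Weibull(shape, scale) conditioned on exceeding ``minimum`` (cm)."""
    if shape <= 0 or scale <= 0:
        raise ValueError("Weibull shape and scale must be positive")
    f_min = 1.0 - math.exp(-((minimum / scale) ** shape))
    u = rng.uniform(f_min, 1.0, size=n)
    return scale * (-np.log1p(-u)) ** (1.0 / shape)


def _hypsometric_height(rng, dbh, params):
    """Monotone saturating height-diameter curve plus Gaussian noise."""
    h_max = params.get("h_max", 22.0)
    dbh_half = params.get("dbh_half", 16.0)
    noise_sd = params.get("noise_sd", 1.0)
    if h_max <= 1.3 or dbh_half <= 0 or noise_sd < 0:
        raise ValueError("invalid hypsometric parameters")
    mean_h = 1.3 + (h_max - 1.3) * dbh / (dbh + dbh_half)
    h = mean_h + rng.normal(0.0, noise_sd, size=dbh.shape)
    return np.maximum(h, 1.5)


def generate_stand(
    extent,
    stem_density: float,
    dbh_distribution: dict | None = None,
    hypsometric_params: dict | None = None,
    seed: int = 0,
    allometry=(0.0613, 0.976),
    fertility=None,
) -> pd.DataFrame:
    """Generate a tree list over ``extent`` (stems/ha Poisson process).

    ``fertility`` is an optional callable f(x, y) in (0, ~2] modulating
    local stem density (by thinning) and diameter scale, giving the spatial
    AGB heterogeneity an area-based inventory relies on.

    Returns a DataFrame with columns x, y, dbh (cm), height (m), species,
    crown_radius (m), agb (kg); all DBH >= the configured minimum.
    """
    if stem_density < 0:
        raise ValueError("stem_density must be >= 0 (stems/ha)")
    dist = {"shape": 1.3, "scale": 9.0, "min_dbh": MIN_DBH_CM}
    dist.update(dbh_distribution or {})
    hyps = hypsometric_params or {}
    xmin, ymin, xmax, ymax = map(float, extent)
    area_ha = (xmax - xmin) * (ymax - ymin) / 1e4
    rng = np.random.default_rng(seed)
    cols = ["x", "y", "dbh", "height", "species", "crown_radius", "agb"]
    # inhomogeneous Poisson by thinning a parent process at twice the target
    # density (fertility is bounded by 2), keeping the realized mean density
    # equal to stem_density when the fertility field averages to one
    parent_factor = 2.0 if fertility is not None else 1.0
    n = rng.poisson(stem_density * area_ha * parent_factor)
    if n == 0:
        return pd.DataFrame({c: [] for c in cols})
    x = rng.uniform(xmin, xmax, n)
    y = rng.uniform(ymin, ymax, n)
    fert = np.ones(n)
    if fertility is not None:
        fert = np.minimum(np.asarray(fertility(x, y), dtype=float), parent_factor)
        keep = rng.uniform(0, parent_factor, n) < fert
        x, y, fert = x[keep], y[keep], fert[keep]
        n = x.size
        if n == 0:
            return pd.DataFrame({c: [] for c in cols})
    dbh = _sample_truncated_weibull(
        rng, n, dist["shape"], dist["scale"], dist["min_dbh"]
    )
    # richer sites carry slightly larger diameters
    dbh = dist["min_dbh"] + (dbh - dist["min_dbh"]) * fert**0.4
    height = _hypsometric_height(rng, dbh, hyps)
    species = rng.choice(SPECIES_POOL, size=n, p=SPECIES_WEIGHTS)
    crown_radius = np.minimum(0.8 + 0.09 * dbh, 6.0)
    agb = allometric_agb(dbh, height, *allometry)
    return pd.DataFrame(
        {
            "x": x, "y": y, "dbh": dbh, "height": height,
            "species": species, "crown_radius": crown_radius, "agb": agb,
        }
    )


# ---------------------------------------------------------------------------
# crown geometry and canopy cover truth
# ---------------------------------------------------------------------------

CROWN_DEPTH_FRACTION = 0.45  # crown depth as a fraction of tree height


def _crown_surface_heights(trees: pd.DataFrame, px, py, tree_ground):
    """Max crown-envelope height above ground at pulse positions.

    Crowns are vertical-axis spheroids of horizontal semi-axis
    ``crown_radius`` and vertical semi-axis ``depth/2`` hung below the tree
    top.  Returns (crown_h, hit_mask): for each pulse, the height above the
    local ground of the highest covering crown surface, -inf if uncovered.
    """
    n = len(px)
    crown_h = np.full(n, -np.inf)
    if len(trees) == 0 or n == 0:
        return crown_h, np.zeros(n, bool)
    kd = cKDTree(np.column_stack([px, py]))
    tx = trees["x"].to_numpy()
    ty = trees["y"].to_numpy()
    th = trees["height"].to_numpy()
    tr = trees["crown_radius"].to_numpy()
    depth = CROWN_DEPTH_FRACTION * th
    zc = th - depth / 2.0  # crown centre height above tree ground
    lists = kd.query_ball_point(np.column_stack([tx, ty]), tr)
    for i, idx in enumerate(lists):
        if not idx:
            continue
        idx = np.asarray(idx)
        d2 = (px[idx] - tx[i]) ** 2 + (py[idx] - ty[i]) ** 2
        u2 = d2 / tr[i] ** 2
        u2 = np.minimum(u2, 1.0)
        surf = zc[i] + (depth[i] / 2.0) * np.sqrt(1.0 - u2)
        np.maximum.at(crown_h, idx, surf)
    return crown_h, np.isfinite(crown_h)


def true_canopy_cover(
    trees: pd.DataFrame,
    grid: GridFramework,
    cell_ids,
    samples_per_cell: int = 3000,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo vertical-projection canopy cover per grid cell."""
    rng = np.random.default_rng(seed)
    cell_ids = np.asarray(cell_ids)
    # one batched point-in-crown query over all cells' sample points
    bounds = np.array([grid.cell_bounds(cid) for cid in cell_ids])
    m = samples_per_cell
    u = rng.uniform(0, 1, (cell_ids.size, m))
    v = rng.uniform(0, 1, (cell_ids.size, m))
    px = (bounds[:, 0, None] + u * (bounds[:, 2] - bounds[:, 0])[:, None]).ravel()
    py = (bounds[:, 1, None] + v * (bounds[:, 3] - bounds[:, 1])[:, None]).ravel()
    _, hit = _crown_surface_heights(trees, px, py, None)
    return hit.reshape(cell_ids.size, m).mean(axis=1)


# ---------------------------------------------------------------------------
# lidar point-cloud simulation
# ---------------------------------------------------------------------------


def simulate_point_cloud(
    trees: pd.DataFrame,
    terrain: TerrainModel,
    point_density: float = 300.0,
    canopy_penetration: float = 0.35,
    vertical_noise_sd: float = 0.05,
    seed: int = 0,
    extent=None,
) -> PointCloud:
    """Simulate a discrete-return lidar cloud over ``extent``.

    Pulses arrive as a uniform Poisson process at ``point_density`` pulses
    per m^2.  A pulse covered by a crown produces a first return on the
    highest crown envelope; with probability ``canopy_penetration`` it also
    produces a second return from the ground.  Uncovered pulses return once
    from the ground.  All z values carry Gaussian noise.  ``truth_class``
    records the generator's own ground/canopy label.
    """
    if point_density <= 0:
        raise ValueError("point_density must be positive (pts/m^2)")
    if not 0.0 <= canopy_penetration <= 1.0:
        raise ValueError("canopy_penetration must be within [0, 1]")
    ext = extent if extent is not None else terrain.extent
    xmin, ymin, xmax, ymax = map(float, ext)
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("empty extent")
    rng = np.random.default_rng(seed)
    area = (xmax - xmin) * (ymax - ymin)
    n_pulses = rng.poisson(point_density * area)
    px = rng.uniform(xmin, xmax, n_pulses)
    py = rng.uniform(ymin, ymax, n_pulses)
    ground_z = terrain.elevation(px, py)
    crown_h, hit = _crown_surface_heights(trees, px, py, None)

    # first returns: crown surface where covered, else ground
    z_first = np.where(hit, ground_z + np.where(hit, crown_h, 0.0), ground_z)
    noise1 = rng.normal(0.0, vertical_noise_sd, n_pulses)
    xs = [px]
    ys = [py]
    zs = [z_first + noise1]
    rns = [np.ones(n_pulses, dtype=np.int16)]
    truth = [np.where(hit, "canopy", "ground")]

    # ground second returns for penetrating canopy pulses
    pen = hit & (rng.uniform(0, 1, n_pulses) < canopy_penetration)
    n2 = int(pen.sum())
    if n2:
        xs.append(px[pen])
        ys.append(py[pen])
        zs.append(ground_z[pen] + rng.normal(0.0, vertical_noise_sd, n2))
        rns.append(np.full(n2, 2, dtype=np.int16))
        truth.append(np.full(n2, "ground", dtype=object))

    return PointCloud(
        x=np.concatenate(xs),
        y=np.concatenate(ys),
        z=np.concatenate(zs),
        return_number=np.concatenate(rns),
        classification=np.full(
            sum(len(a) for a in xs), CLASS_UNCLASSIFIED, dtype=np.uint8
        ),
        truth_class=np.concatenate([np.asarray(t, dtype=object) for t in truth]),
    )


# ---------------------------------------------------------------------------
# reflectance
# ---------------------------------------------------------------------------


def fractions_from_cover(cover: np.ndarray) -> pd.DataFrame:
    """Deterministic endmember fractions as a function of canopy cover.

    Denser canopies mix more green vegetation and internal shadow; open
    ground splits between dry vegetation and bare soil.  Fractions are
    non-negative and sum to one exactly.
    """
    cover = np.clip(np.asarray(cover, dtype=float), 0.0, 1.0)
    gv = 0.80 * cover + 0.02
    shade = 0.15 * cover
    rest = 1.0 - gv - shade
    npv = 0.45 * rest
    soil = rest - npv
    return pd.DataFrame({"GV": gv, "NPV": npv, "Soil": soil, "Shade": shade})


def biophysical_truth(cover: np.ndarray, extinction_k: float = 0.5) -> pd.DataFrame:
    """True LAI / FAPAR / FCOVER / CAB per cell from canopy cover."""
    cover = np.clip(np.asarray(cover, dtype=float), 0.0, 1.0)
    lai = -np.log(1.0 - 0.95 * cover) / extinction_k
    fapar = np.clip(1.0 - np.exp(-extinction_k * lai), 0.0, 1.0)
    return pd.DataFrame(
        {"LAI": lai, "FAPAR": fapar, "FCOVER": cover, "CAB": 15.0 + 45.0 * cover}
    )


def simulate_reflectance(
    scene_truth: pd.DataFrame,
    endmembers: EndmemberLibrary | None = None,
    band_noise_sd: float = 0.01,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell reflectance = fraction-weighted endmember mixture + noise.

    ``scene_truth`` must contain columns GV, NPV, Soil, Shade (non-negative,
    summing to one per cell).  Output is clipped to [0, 1].
    """
    endmembers = endmembers or default_endmembers()
    fr = scene_truth[list(ENDMEMBER_NAMES)].to_numpy(dtype=float)
    if np.any(fr < -1e-12):
        raise ValueError("endmember fractions must be non-negative")
    if np.any(np.abs(fr.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("endmember fractions must sum to 1 per cell")
    E = endmembers.matrix()  # bands x endmembers
    refl = fr @ E.T
    if band_noise_sd > 0:
        rng = np.random.default_rng(seed)
        refl = refl + rng.normal(0.0, band_noise_sd, refl.shape)
    refl = np.clip(refl, 0.0, 1.0)
    out = pd.DataFrame(refl, columns=list(BAND_NAMES))
    if "cell_id" in scene_truth.columns:
        out.insert(0, "cell_id", scene_truth["cell_id"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# block / plot layout
# ---------------------------------------------------------------------------


def layout_blocks_and_plots(
    grid: GridFramework,
    n_blocks: int = 10,
    block_area_range=(30.0, 50.0),  # hectares
    plots_per_block=(10, 12),
    plot_spacing: float = 250.0,
    border_buffer: float = 50.0,
    seed: int = 0,
    max_tries: int = 2000,
    block_aspect_range=(0.6, 1.6),
    allow_fewer_plots: bool = False,
):
    """Place rectangular flight blocks and circular-plot centres.

    Blocks are grid-aligned, non-overlapping rectangles whose area falls in
    ``block_area_range``.  Plot centres coincide with 20 m cell centres, lie
    at least ``border_buffer`` from the block edge and pairwise at least
    ``plot_spacing`` apart within each block.

    Returns (blocks, plots): ``blocks`` is a DataFrame (block_id, xmin,
    ymin, xmax, ymax) and ``plots`` a DataFrame (plot_id, block_id, x, y,
    cell_id).  Raises ``ValueError`` naming the achieved count when the
    requested packing is infeasible.
    """
    rng = np.random.default_rng(seed)
    cs = grid.cell_size
    gxmin, gymin, gxmax, gymax = grid.extent
    if isinstance(plots_per_block, int):
        plots_per_block = (plots_per_block, plots_per_block)

    # sample grid-aligned block dimensions first
    lo, hi = block_area_range
    dims = []
    for _ in range(n_blocks):
        area_m2 = rng.uniform(lo, hi) * 1e4
        aspect = rng.uniform(*block_aspect_range)
        w = max(round(math.sqrt(area_m2 * aspect) / cs), 1) * cs
        h = max(round((area_m2 / w) / cs), 1) * cs
        if w > gxmax - gxmin or h > gymax - gymin:
            raise ValueError(
                f"a {w:.0f} x {h:.0f} m block does not fit in the extent"
            )
        dims.append((w, h))

    # place blocks into a jittered slot lattice (one cell of separation);
    # fall back to rejection sampling when the lattice is too coarse
    wmax = max(d[0] for d in dims) + cs
    hmax = max(d[1] for d in dims) + cs
    sx = int((gxmax - gxmin) // wmax)
    sy = int((gymax - gymin) // hmax)
    placed = []
    if sx * sy >= n_blocks:
        slots = [(i, j) for i in range(sx) for j in range(sy)]
        chosen = rng.permutation(len(slots))[:n_blocks]
        for b, si in enumerate(chosen):
            i, j = slots[si]
            w, h = dims[b]
            x_lo = gxmin + i * wmax
            y_lo = gymin + j * hmax
            jx = rng.integers(0, int((wmax - w) / cs) + 1) * cs
            jy = rng.integers(0, int((hmax - h) / cs) + 1) * cs
            placed.append((x_lo + jx, y_lo + jy, x_lo + jx + w, y_lo + jy + h))
    else:
        for b, (w, h) in enumerate(dims):
            ok = False
            for _ in range(max_tries):
                x0 = gxmin + rng.integers(0, int((gxmax - gxmin - w) / cs) + 1) * cs
                y0 = gymin + rng.integers(0, int((gymax - gymin - h) / cs) + 1) * cs
                cand = (x0, y0, x0 + w, y0 + h)
                separated = all(
                    cand[2] + cs <= p[0] or p[2] + cs <= cand[0]
                    or cand[3] + cs <= p[1] or p[3] + cs <= cand[1]
                    for p in placed
                )
                if separated:
                    placed.append(cand)
                    ok = True
                    break
            if not ok:
                raise ValueError(
                    f"could not place block {b + 1} of {n_blocks}; "
                    f"achieved {len(placed)} blocks"
                )

    blocks = pd.DataFrame(
        placed, columns=["xmin", "ymin", "xmax", "ymax"]
    )
    blocks.insert(0, "block_id", np.arange(len(placed)))

    plot_rows = []
    pid = 0
    for _, blk in blocks.iterrows():
        n_target = int(rng.integers(plots_per_block[0], plots_per_block[1] + 1))
        # candidate cell centres at least border_buffer inside the block
        cols = np.arange(
            math.ceil((blk.xmin + border_buffer - grid.origin_x - cs / 2) / cs),
            math.floor((blk.xmax - border_buffer - grid.origin_x - cs / 2) / cs) + 1,
        )
        rows_s = np.arange(
            math.ceil((blk.ymin + border_buffer - grid.origin_y - cs / 2) / cs),
            math.floor((blk.ymax - border_buffer - grid.origin_y - cs / 2) / cs) + 1,
        )
        cx = grid.origin_x + (cols + 0.5) * cs
        cy = grid.origin_y + (rows_s + 0.5) * cs
        cand = np.array([(x, y) for x in cx for y in cy])
        if cand.size == 0:
            raise ValueError(
                f"block {int(blk.block_id)}: no candidate plot centres inside buffer"
            )
        chosen = []
        for _ in range(60):  # randomized greedy with restarts
            order = rng.permutation(len(cand))
            trial = []
            for i in order:
                p = cand[i]
                if all(np.hypot(*(p - q)) >= plot_spacing - 1e-9 for q in trial):
                    trial.append(p)
                    if len(trial) == n_target:
                        break
            if len(trial) > len(chosen):
                chosen = trial
            if len(chosen) == n_target:
                break
        if len(chosen) < n_target:
            if not allow_fewer_plots:
                raise ValueError(
                    f"block {int(blk.block_id)}: requested {n_target} plots at "
                    f"{plot_spacing} m spacing, achieved {len(chosen)}"
                )
            import warnings

            warnings.warn(
                f"block {int(blk.block_id)}: packing allows only {len(chosen)} "
                f"of {n_target} plots at {plot_spacing} m spacing"
            )
        for p in chosen:
            plot_rows.append(
                (pid, int(blk.block_id), p[0], p[1], int(grid.point_to_cell(p[0], p[1])))
            )
            pid += 1
    plots = pd.DataFrame(
        plot_rows, columns=["plot_id", "block_id", "x", "y", "cell_id"]
    )
    return blocks, plots


def plot_agb_mgha(trees: pd.DataFrame, plot_x, plot_y, radius: float = 10.0):
    """Field-plot AGB (Mg/ha): sum of tree kg within the circle / plot area."""
    if len(trees) == 0:
        return np.zeros(np.size(plot_x))
    kd = cKDTree(trees[["x", "y"]].to_numpy())
    area_ha = math.pi * radius**2 / 1e4
    agb = trees["agb"].to_numpy()
    out = np.zeros(np.size(plot_x))
    pts = np.column_stack([np.atleast_1d(plot_x), np.atleast_1d(plot_y)])
    for j, idx in enumerate(kd.query_ball_point(pts, radius)):
        out[j] = agb[idx].sum() / 1000.0 / area_ha
    return out


# ---------------------------------------------------------------------------
# whole-scene generation
# ---------------------------------------------------------------------------


@dataclass
class SceneConfig:
    """Study-scene configuration; defaults mirror the field campaign design
    (10 flight blocks of 30-50 ha inside an ~8100 ha extent, 10-12 circular
    10 m plots per block at 250 m spacing and a 50 m border buffer, 20 m
    grid, 300 pulses/m^2).  Smaller test scenes override sizes explicitly.
    """

    extent: tuple = (0.0, 0.0, 9000.0, 9000.0)
    cell_size: float = 20.0
    relief_amplitude: float = 8.0
    correlation_length: float = 300.0
    stem_density: float = 550.0  # stems/ha with DBH >= 5 cm
    dbh_shape: float = 1.3
    dbh_scale: float = 11.0
    min_dbh: float = MIN_DBH_CM
    h_max: float = 22.0
    dbh_half: float = 16.0
    height_noise_sd: float = 1.0
    allometry_a: float = 0.0613
    allometry_b: float = 0.976
    fertility_strength: float = 0.6
    fertility_length: float = 250.0
    n_blocks: int = 10
    block_area_range: tuple = (30.0, 50.0)
    block_aspect_range: tuple = (0.6, 1.6)
    plots_per_block: tuple = (10, 12)
    plot_spacing: float = 250.0
    border_buffer: float = 50.0
    plot_radius: float = 10.0
    point_density: float = 300.0  # pulses/m^2
    canopy_penetration: float = 0.35
    vertical_noise_sd: float = 0.05
    band_noise_sd: float = 0.01
    plot_agb_noise_cv: float = 0.15  # field AGB observation error (allometric + measurement)
    cover_samples_per_cell: int = 2000
    seed: int = 0


@dataclass
class Scene:
    """A generated study scene: everything the pipeline downstream needs."""

    config: SceneConfig
    grid: GridFramework
    terrain: TerrainModel
    trees: pd.DataFrame
    blocks: pd.DataFrame
    plots: pd.DataFrame  # plot_id, block_id, x, y, cell_id, agb_mgha
    truth: pd.DataFrame  # per cell: cell_id, in_block, agb, cover, fractions, BVs
    reflectance: pd.DataFrame  # per cell: cell_id + 10 bands
    cloud: PointCloud | None


def _block_cell_ids(grid: GridFramework, blocks: pd.DataFrame) -> np.ndarray:
    """Ids of grid cells fully inside any block rectangle."""
    ids = []
    cs = grid.cell_size
    for _, blk in blocks.iterrows():
        cols = np.arange(
            int(round((blk.xmin - grid.origin_x) / cs)),
            int(round((blk.xmax - grid.origin_x) / cs)),
        )
        rows_s = np.arange(
            int(round((blk.ymin - grid.origin_y) / cs)),
            int(round((blk.ymax - grid.origin_y) / cs)),
        )
        for c in cols:
            for r in rows_s:
                row = grid.n_rows - 1 - r
                if 0 <= c < grid.n_cols and 0 <= row < grid.n_rows:
                    ids.append(row * grid.n_cols + c)
    return np.unique(np.asarray(ids, dtype=np.int64))


def generate_scene(config: SceneConfig | None = None, simulate_cloud: bool = True) -> Scene:
    """Generate a full synthetic study scene from one seeded configuration."""
    cfg = config or SceneConfig()
    root = np.random.SeedSequence(cfg.seed)
    seeds = root.spawn(6)

    grid = make_fishnet(cfg.extent, cfg.cell_size)
    terrain = generate_terrain(
        cfg.extent, cfg.relief_amplitude, cfg.correlation_length,
        seed=seeds[0].generate_state(1)[0] % (2**31),
    )
    fert_field = generate_terrain(
        cfg.extent, 1.0, cfg.fertility_length,
        seed=seeds[1].generate_state(1)[0] % (2**31), base_elevation=0.0,
    )

    def fertility(x, y):
        return np.clip(1.0 + cfg.fertility_strength * fert_field.elevation(x, y), 0.05, None)

    trees = generate_stand(
        cfg.extent,
        cfg.stem_density,
        {"shape": cfg.dbh_shape, "scale": cfg.dbh_scale, "min_dbh": cfg.min_dbh},
        {"h_max": cfg.h_max, "dbh_half": cfg.dbh_half, "noise_sd": cfg.height_noise_sd},
        seed=seeds[2].generate_state(1)[0] % (2**31),
        allometry=(cfg.allometry_a, cfg.allometry_b),
        fertility=fertility if cfg.fertility_strength > 0 else None,
    )

    blocks, plots = layout_blocks_and_plots(
        grid, cfg.n_blocks, cfg.block_area_range, cfg.plots_per_block,
        cfg.plot_spacing, cfg.border_buffer,
        seed=seeds[3].generate_state(1)[0] % (2**31),
        block_aspect_range=cfg.block_aspect_range,
        allow_fewer_plots=True,
    )
    plots["agb_mgha"] = plot_agb_mgha(
        trees, plots["x"].to_numpy(), plots["y"].to_numpy(), cfg.plot_radius
    )
    if cfg.plot_agb_noise_cv > 0:
        # field AGB is an allometric estimate, not truth: multiplicative
        # lognormal observation error with the configured CV
        rng_obs = np.random.default_rng(np.random.SeedSequence([cfg.seed, 104729]).generate_state(1)[0])
        cv = cfg.plot_agb_noise_cv
        sigma = math.sqrt(math.log(1.0 + cv**2))
        plots["agb_mgha"] *= rng_obs.lognormal(-sigma**2 / 2.0, sigma, len(plots))

    # per-cell truth over the whole framework
    all_ids = grid.all_cell_ids()
    block_ids = _block_cell_ids(grid, blocks)
    cover = true_canopy_cover(
        trees, grid, all_ids, cfg.cover_samples_per_cell,
        seed=seeds[4].generate_state(1)[0] % (2**31),
    )
    cell_x, cell_y = grid.cell_center(all_ids)
    if len(trees):
        tree_cells = grid.point_to_cell(trees["x"].to_numpy(), trees["y"].to_numpy())
        agb_kg = np.zeros(grid.n_cells)
        ok = tree_cells >= 0
        np.add.at(agb_kg, tree_cells[ok], trees["agb"].to_numpy()[ok])
    else:
        agb_kg = np.zeros(grid.n_cells)
    cell_area_ha = cfg.cell_size**2 / 1e4
    truth = pd.DataFrame(
        {
            "cell_id": all_ids,
            "x_center": cell_x,
            "y_center": cell_y,
            "in_block": np.isin(all_ids, block_ids),
            "agb_mgha": agb_kg / 1000.0 / cell_area_ha,
            "cover": cover,
        }
    )
    truth = pd.concat(
        [truth, fractions_from_cover(cover), biophysical_truth(cover)], axis=1
    )

    reflectance = simulate_reflectance(
        truth, default_endmembers(), cfg.band_noise_sd,
        seed=seeds[5].generate_state(1)[0] % (2**31),
    )

    cloud = None
    if simulate_cloud:
        parts = []
        cloud_root = np.random.SeedSequence([cfg.seed, 7919])
        for sub, (_, blk) in zip(
            cloud_root.spawn(len(blocks)), blocks.iterrows()
        ):
            margin = 6.0  # crowns overhanging block edges
            sub_ext = (blk.xmin, blk.ymin, blk.xmax, blk.ymax)
            tsel = trees[
                (trees.x >= blk.xmin - margin) & (trees.x <= blk.xmax + margin)
                & (trees.y >= blk.ymin - margin) & (trees.y <= blk.ymax + margin)
            ]
            parts.append(
                simulate_point_cloud(
                    tsel, terrain, cfg.point_density, cfg.canopy_penetration,
                    cfg.vertical_noise_sd,
                    seed=sub.generate_state(1)[0] % (2**31),
                    extent=sub_ext,
                )
            )
        cloud = PointCloud.concatenate(parts)

    return Scene(cfg, grid, terrain, trees, blocks, plots, truth, reflectance, cloud)
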