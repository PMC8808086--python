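"""Predictor engineering: terrain indices, landmass shape, locality
statistics, diversity trajectories, and the transform onto the analysis grid.

All predictors end up as :class:`~paleodrivers.containers.PredictorSeries`
on a 0.1 Myr age grid, linearly interpolated, log10-transformed (after an
automatic positivity shift where needed) and z-scored so that the
birth-death coefficient scales are comparable across predictors.

The Tectonic Complexity Index (TCI) combines the shoreline development of
a landmass outline, D = P / (2 sqrt(pi A)), with the mean terrain
ruggedness index (TRI) of its interior:

    TCI = [P / (2 sqrt(A pi))] * TRI

D is 1 for a circle, so a circular continent has TCI equal to its TRI;
a flat continent (TRI = 0) has TCI 0 regardless of outline.  The index is
in the units of the TRI (metres here) and is unbounded above.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage import measure

from .containers import (
    GRID_STEP,
    ElevationGrid,
    LocalityTable,
    PredictorSeries,
    ReplicateSet,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "compute_tri",
    "extract_landmass_shape",
    "shoreline_development",
    "compute_tci",
    "mean_pairwise_distance",
    "basin_stats",
    "diversity_trajectory",
    "continental_area",
    "elevation_range",
    "standardize_series",
    "subsample_localities",
    "EARTH_RADIUS_KM",
]

EARTH_RADIUS_KM = 6371.0

#: Gaussian pre-smoothing (in cells) applied to the land mask before the
#: marching-squares contour trace; removes the staircase bias of raw
#: marching squares on rasterized shapes.
_CONTOUR_SIGMA = 0.8


# ---------------------------------------------------------------------------
# terrain ruggedness


def _tri_per_cell(grid: ElevationGrid) -> np.ndarray:
    """Riley TRI per land cell (NaN where not evaluable).

    TRI(cell) = sqrt( sum over up-to-8 land neighbours of the squared
    elevation difference to the cell ).  Sea neighbours are ignored.
    """
    elev = np.where(grid.mask, grid.elevation, np.nan)
    nrows, ncols = elev.shape
    sq = np.zeros_like(elev)
    has_nbr = np.zeros(elev.shape, dtype=bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            nbr = np.full_like(elev, np.nan)
            rs = slice(max(dr, 0), nrows + min(dr, 0))
            rd = slice(max(-dr, 0), nrows + min(-dr, 0))
            cs = slice(max(dc, 0), ncols + min(dc, 0))
            cd = slice(max(-dc, 0), ncols + min(-dc, 0))
            nbr[rd, cd] = elev[rs, cs]
            diff = elev - nbr
            valid = ~np.isnan(diff)
            sq[valid] += diff[valid] ** 2
            has_nbr |= valid
    tri = np.sqrt(sq)
    tri[~has_nbr] = np.nan
    tri[~grid.mask] = np.nan
    return tri


def compute_tri(
    grid: ElevationGrid, cells: Sequence[tuple[int, int]] | None = None
) -> float:
    """Mean terrain ruggedness index (metres).

    ``cells`` restricts the mean to listed (row, col) cells — the mode used
    for "ruggedness at fossil localities"; ``None`` averages all land cells
    with at least one land neighbour.
    """
    tri = _tri_per_cell(grid)
    if cells is not None:
        vals = np.array([tri[r, c] for r, c in cells], dtype=float)
    else:
        vals = tri[~np.isnan(tri)]
    vals = vals[~np.isnan(vals)] if cells is not None else vals
    if vals.size == 0:
        raise ValidationError("no evaluable land cell for TRI")
    return float(vals.mean())


# ---------------------------------------------------------------------------
# landmass shape


def extract_landmass_shape(grid: ElevationGrid) -> tuple[float, float]:
    """Perimeter P (km) and area A (km^2) of all landmasses in the grid.

    A counts land cells; P traces the land/sea boundary with marching
    squares on a lightly smoothed mask field, summing over every separate
    landmass and any interior sea (holes).
    """
    if grid.n_land == 0:
        raise ValidationError("empty land mask")
    area = grid.n_land * grid.cellsize**2
    padded = np.pad(grid.mask.astype(float), 4)
    smooth = gaussian_filter(padded, _CONTOUR_SIGMA)
    perim_cells = 0.0
    for contour in measure.find_contours(smooth, 0.5):
        d = np.diff(contour, axis=0)
        perim_cells += float(np.hypot(d[:, 0], d[:, 1]).sum())
    return perim_cells * grid.cellsize, area


def shoreline_development(perimeter: float, area: float) -> float:
    """Shoreline development D = P / (2 sqrt(pi A)); 1 for a circle."""
    if perimeter <= 0 or area <= 0:
        raise ValidationError("perimeter and area must be positive")
    return perimeter / (2.0 * np.sqrt(np.pi * area))


def compute_tci(perimeter: float, area: float, tri: float) -> float:
    """Tectonic complexity index: shoreline development times mean TRI."""
    if tri < 0:
        raise ValidationError("TRI must be non-negative")
    if tri == 0:
        # a flat landmass has no tectonic complexity regardless of outline
        if perimeter <= 0 or area <= 0:
            raise ValidationError("perimeter and area must be positive")
        return 0.0
    return shoreline_development(perimeter, area) * tri


# ---------------------------------------------------------------------------
# locality statistics


def haversine_km(
    lon1: np.ndarray, lat1: np.ndarray, lon2: np.ndarray, lat2: np.ndarray
) -> np.ndarray:
    """Great-circle distance (km) on a sphere of radius 6371 km."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def mean_pairwise_distance(
    localities: LocalityTable, slice_bounds: tuple[float, float]
) -> float:
    """Mean great-circle distance (km) over all unordered locality pairs
    in the half-open age slice [young, old).

    Returns NaN (logged) when the slice has fewer than two localities.
    """
    young, old = slice_bounds
    sub = localities.in_slice(young, old)
    n = len(sub)
    if n < 2:
        logger.info(
            "slice [%s, %s) has %d localities; mean distance undefined",
            young, old, n,
        )
        return float("nan")
    lon = sub["lon"].to_numpy()
    lat = sub["lat"].to_numpy()
    iu, ju = np.triu_indices(n, k=1)
    d = haversine_km(lon[iu], lat[iu], lon[ju], lat[ju])
    return float(d.mean())


def basin_stats(
    localities: LocalityTable,
    basin_areas: dict[str, float],
    slice_bounds: tuple[float, float],
) -> tuple[int, float]:
    """(number of occupied basins, mean occupied-basin area in km^2).

    Each basin counts once no matter how many localities it holds; an
    empty slice yields (0, NaN).
    """
    young, old = slice_bounds
    sub = localities.in_slice(young, old)
    basins = sorted(set(sub["basin_id"]))
    if not basins:
        return 0, float("nan")
    missing = [b for b in basins if b not in basin_areas]
    if missing:
        raise ValidationError(f"no area entry for basin(s): {missing}")
    areas = np.array([basin_areas[b] for b in basins], dtype=float)
    return len(basins), float(areas.mean())


# ---------------------------------------------------------------------------
# diversity and elevation


def diversity_trajectory(
    replicates: ReplicateSet, t_max: float, step: float = GRID_STEP
) -> PredictorSeries:
    """Mean standing richness N(t) across replicates on the age grid.

    A species is alive at age t when te <= t < ts (half-open, so no
    double-count at its own origination age).
    """
    ages = np.round(np.arange(0.0, t_max + step / 2, step), 9)
    counts = np.zeros((len(replicates), len(ages)))
    for i, table in enumerate(replicates):
        counts[i] = table.lineage_count(ages)
    return PredictorSeries(name="diversity", ages=ages, raw=counts.mean(axis=0))


def continental_area(grid: ElevationGrid) -> float:
    """Total land area in km^2 (0 for an all-sea grid)."""
    return float(grid.n_land) * grid.cellsize**2


def elevation_range(
    grid: ElevationGrid, cells: Sequence[tuple[int, int]]
) -> float:
    """Mean local elevation range (m) over the listed cells.

    The local range of a cell is max - min elevation within its 3x3
    land neighbourhood (the cell included).
    """
    elev = np.where(grid.mask, grid.elevation, np.nan)
    nrows, ncols = elev.shape
    ranges = []
    for r, c in cells:
        if not (0 <= r < nrows and 0 <= c < ncols) or not grid.mask[r, c]:
            continue
        block = elev[max(r - 1, 0): r + 2, max(c - 1, 0): c + 2]
        vals = block[~np.isnan(block)]
        ranges.append(float(vals.max() - vals.min()))
    if not ranges:
        raise ValidationError("no listed land cell for elevation range")
    return float(np.mean(ranges))


def mean_elevation(grid: ElevationGrid, cells: Sequence[tuple[int, int]]) -> float:
    """Mean elevation (m) at the listed land cells (alternative statistic
    to :func:`elevation_range`; see docs/methods.md)."""
    vals = [
        float(grid.elevation[r, c])
        for r, c in cells
        if 0 <= r < grid.shape[0] and 0 <= c < grid.shape[1] and grid.mask[r, c]
    ]
    if not vals:
        raise ValidationError("no listed land cell")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# transform onto the analysis grid


def fill_undefined_slices(values: np.ndarray) -> np.ndarray:
    """Fill NaN slice values by linear interpolation from neighbours
    (flat at the ends); logged so gaps are auditable."""
    values = np.asarray(values, dtype=float)
    nan = np.isnan(values)
    if nan.all():
        raise ValidationError("all slice values undefined")
    if nan.any():
        logger.info("interpolating %d undefined slice value(s)", nan.sum())
        idx = np.arange(len(values))
        values = values.copy()
        values[nan] = np.interp(idx[nan], idx[~nan], values[~nan])
    return values


def standardize_series(
    ages_raw: np.ndarray,
    values_raw: np.ndarray,
    t_max: float,
    name: str = "",
    step: float = GRID_STEP,
    log_transform: bool = True,
) -> PredictorSeries:
    """Interpolate to the analysis grid, log10-transform, z-score.

    Linear interpolation with flat extrapolation beyond the endpoints;
    series containing non-positive values get an automatic positivity
    shift of (1 - min) before the log; a constant series degenerates to
    all-zero transformed values (with a warning) rather than dividing by
    a zero standard deviation.
    """
    ages_raw = np.asarray(ages_raw, dtype=float)
    values_raw = np.asarray(values_raw, dtype=float)
    if ages_raw.size == 0:
        raise ValidationError("empty predictor input")
    order = np.argsort(ages_raw)
    ages_raw, values_raw = ages_raw[order], values_raw[order]
    grid = np.round(np.arange(0.0, t_max + step / 2, step), 9)
    interp = np.interp(grid, ages_raw, values_raw)
    x = interp
    if log_transform:
        mn = x.min()
        if mn <= 0:
            x = x + (1.0 - mn)
        x = np.log10(x)
    sd = x.std()
    if sd < 1e-12:
        warnings.warn(
            f"predictor {name!r} is constant; transformed values set to 0",
            stacklevel=2,
        )
        z = np.zeros_like(x)
    else:
        z = (x - x.mean()) / sd
    return PredictorSeries(name=name, ages=grid, raw=interp, transformed=z)


def slice_series_to_grid(
    slice_ages: np.ndarray,
    slice_values: np.ndarray,
    t_max: float,
    name: str = "",
    step: float = GRID_STEP,
    log_transform: bool = True,
) -> PredictorSeries:
    """Per-Myr-slice statistics -> filled, interpolated, standardized series."""
    values = fill_undefined_slices(slice_values)
    return standardize_series(
        slice_ages, values, t_max, name=name, step=step,
        log_transform=log_transform,
    )


# ---------------------------------------------------------------------------
# subsampling


def subsample_localities(
    localities: LocalityTable,
    fraction: float,
    scheme: str = "uniform",
    seed: int | None = None,
) -> LocalityTable:
    """Subsample localities to test sensitivity to spatial coverage.

    ``uniform`` draws a simple random sample of rows; ``spatial-block``
    drops whole basins (never splitting one) until at most ``fraction``
    of the localities remain.
    """
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return localities
    rng = np.random.default_rng(seed)
    df = localities.data
    if scheme == "uniform":
        n_keep = int(round(fraction * len(df)))
        idx = rng.choice(len(df), size=n_keep, replace=False)
        return LocalityTable(df.iloc[np.sort(idx)])
    if scheme == "spatial-block":
        target = fraction * len(df)
        basins = list(pd.unique(df["basin_id"]))
        rng.shuffle(basins)
        kept = set(basins)
        counts = df["basin_id"].value_counts()
        total = len(df)
        for b in basins:
            if total <= target:
                break
            kept.discard(b)
            total -= int(counts[b])
        return LocalityTable(df[df["basin_id"].isin(kept)])
    raise ValueError(f"unknown subsampling scheme {scheme!r}")
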