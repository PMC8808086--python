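"""Synthetic data with the statistical structure the windowed birth-death
analysis assumes: lifespans from a covariate-driven birth-death process,
replicate jitter mimicking posterior uncertainty in origination/extinction
times, smooth predictor trajectories, raster landmasses of known geometry,
and spatially clustered fossil localities.

The generative model mirrors the inference model: per-lineage speciation
and extinction rates are

    lambda(t) = lambda0 * exp( sum_j g_lambda_j * x_j(t) )
    mu(t)     = mu0     * exp( sum_j g_mu_j     * x_j(t) )

with x_j standardized predictor series on the 0.1 Myr grid.  Speciation is
budding (the mother persists and a daughter lineage starts), the taxic
convention of species-level fossil birth-death work.  Event times are drawn
by thinning a dominating constant-rate process; because the predictors are
piecewise constant at 0.1 Myr resolution the thinning is exact.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    GRID_STEP,
    ElevationGrid,
    LifespanTable,
    LocalityTable,
    PredictorSeries,
    ReplicateSet,
    ValidationError,
)

__all__ = [
    "SimulationTruth",
    "PredictorTruth",
    "simulate_predictor_series",
    "simulate_bd_lifespans",
    "perturb_replicates",
    "simulate_elevation_grid",
    "simulate_localities",
]


@dataclass(frozen=True)
class SimulationTruth:
    """Generating parameters of a synthetic birth-death dataset."""

    lambda0: float = 0.03          # baseline speciation rate, events/Myr
    mu0: float = 0.025             # baseline extinction rate, events/Myr
    g_lambda: tuple[float, ...] = ()   # per standardized predictor
    g_mu: tuple[float, ...] = ()
    t_start: float = 100.0         # Ma; founders enter here
    n_founders: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda0 < 0 or self.mu0 < 0:
            raise ValidationError("rates must be non-negative")
        if self.t_start <= 0:
            raise ValidationError("t_start must be positive")
        if self.n_founders < 1:
            raise ValidationError("need at least one founder")

    def to_json(self, path: str | Path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)


@dataclass(frozen=True)
class PredictorTruth:
    """Shape of one synthetic predictor trajectory.

    kinds: ``constant`` (value = mean); ``linear`` (mean at t=0, slope per
    Myr into the past); ``ou`` (mean-reverting Gaussian process with
    stationary sd and reversion rate per Myr); ``step`` (levels[i] applies
    between change_points[i-1] and change_points[i], youngest first).
    """

    kind: str = "ou"
    mean: float = 0.0
    sd: float = 1.0
    reversion: float = 0.05
    slope: float = 0.0
    change_points: tuple[float, ...] = ()
    levels: tuple[float, ...] = ()
    grid_step: float = GRID_STEP

    def __post_init__(self) -> None:
        if self.grid_step <= 0:
            raise ValidationError("grid step must be positive")
        if self.kind == "ou" and self.sd <= 0:
            raise ValidationError("OU sd must be positive")
        if self.kind == "step" and len(self.levels) != len(self.change_points) + 1:
            raise ValidationError("step needs len(levels) == len(change_points)+1")


def simulate_predictor_series(
    truth: PredictorTruth, t_start: float, seed: int | None = None,
    name: str = "predictor",
) -> PredictorSeries:
    """Raw predictor trajectory on every grid step of [0, t_start]."""
    if t_start <= 0:
        raise ValidationError("t_start must be positive")
    step = truth.grid_step
    ages = np.round(np.arange(0.0, t_start + step / 2, step), 9)
    if truth.kind == "constant":
        vals = np.full_like(ages, truth.mean)
    elif truth.kind == "linear":
        vals = truth.mean + truth.slope * ages
    elif truth.kind == "step":
        vals = np.full_like(ages, truth.levels[0])
        for cp, level in zip(truth.change_points, truth.levels[1:]):
            vals[ages >= cp] = level
    elif truth.kind == "ou":
        # exact stationary OU transition on the regular grid
        rng = np.random.default_rng(seed)
        n = len(ages)
        vals = np.empty(n)
        phi = np.exp(-truth.reversion * step)
        innov_sd = truth.sd * np.sqrt(1 - phi**2)
        # simulate from the past toward the present for temporal realism
        x = rng.normal(truth.mean, truth.sd)
        vals[n - 1] = x
        noise = rng.normal(0.0, innov_sd, size=n - 1)
        for i in range(n - 2, -1, -1):
            x = truth.mean + phi * (x - truth.mean) + noise[n - 2 - i]
            vals[i] = x
    else:
        raise ValueError(f"unknown predictor kind {truth.kind!r}")
    return PredictorSeries(name=name, ages=ages, raw=vals)


# ---------------------------------------------------------------------------
# birth-death simulation


def _rates_on_grid(
    truth: SimulationTruth, predictors: Sequence[PredictorSeries]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(ages, lambda(t), mu(t)) on the predictor grid (piecewise constant)."""
    p = len(predictors)
    if len(truth.g_lambda) != p or len(truth.g_mu) != p:
        raise ValidationError("coefficient vectors must match predictor count")
    if p == 0:
        ages = np.round(np.arange(0.0, truth.t_start + GRID_STEP / 2, GRID_STEP), 9)
        ones = np.ones_like(ages)
        return ages, truth.lambda0 * ones, truth.mu0 * ones
    ages = predictors[0].ages
    if ages[-1] < truth.t_start - 1e-9:
        raise ValidationError("predictor series do not cover [0, t_start]")
    X = np.column_stack([s.transformed for s in predictors])
    lam = truth.lambda0 * np.exp(X @ np.asarray(truth.g_lambda))
    mu = truth.mu0 * np.exp(X @ np.asarray(truth.g_mu))
    return ages, lam, mu


def simulate_bd_lifespans(
    truth: SimulationTruth,
    predictors: Sequence[PredictorSeries] = (),
    rate_cap: float = 50.0,
    max_species: int = 100_000,
) -> LifespanTable:
    """Simulate species lifespans under the covariate-driven birth-death
    process by exact thinning of a dominating constant-rate process.

    Each founder enters at ``t_start``; daughters bud off with rate
    lambda(t); lineages die with rate mu(t); survivors at the present get
    te = 0 (extant).  Raises if any instantaneous rate exceeds
    ``rate_cap`` (events/Myr) — a symptom of over-large coefficients.
    """
    ages, lam, mu = _rates_on_grid(truth, predictors)
    total = lam + mu
    if np.max(lam) > rate_cap or np.max(mu) > rate_cap:
        raise ValidationError(
            f"instantaneous rate exceeds cap {rate_cap}/Myr; "
            "use smaller coefficients or baselines"
        )
    cap = float(np.max(total))
    rng = np.random.default_rng(truth.seed)
    # rates are piecewise constant per 0.1 Myr cell; index by floor(t/step)
    step = float(np.round(ages[1] - ages[0], 9)) if len(ages) > 1 else GRID_STEP
    ncell = len(ages)

    def rate_at(t: float) -> tuple[float, float]:
        i = min(int(t / step), ncell - 1)
        return lam[i], mu[i]

    rows: list[tuple[str, float, float]] = []
    # stack of (birth_age,) lineages awaiting simulation
    stack = [truth.t_start] * truth.n_founders
    counter = 0
    while stack:
        birth = stack.pop()
        t = birth
        while True:
            if cap == 0.0:
                t = 0.0
            else:
                t -= rng.exponential(1.0 / cap)
            if t <= 0.0:
                te = 0.0
                break
            l_t, m_t = rate_at(t)
            u = rng.uniform()
            if u < l_t / cap:
                stack.append(t)  # budding: daughter starts, mother continues
                if len(stack) + counter > max_species:
                    raise ValidationError(
                        "simulation exceeded max_species; reduce rates"
                    )
            elif u < (l_t + m_t) / cap:
                te = t
                break
        counter += 1
        rows.append((f"sp{counter:05d}", birth, te))
    df = pd.DataFrame(rows, columns=["species_id", "ts", "te"])
    return LifespanTable(df)


def perturb_replicates(
    table: LifespanTable,
    jitter_sd: float,
    n_replicates: int,
    seed: int | None = None,
) -> ReplicateSet:
    """Jittered copies of a lifespan table emulating posterior replicates.

    Gaussian noise (sd in Myr) is added to ts and te, truncated so that
    ts > te >= 0 always holds; te = 0 stays exactly 0 (extant status is
    certain).  jitter_sd = 0 returns exact copies.
    """
    if jitter_sd < 0:
        raise ValidationError("jitter_sd must be non-negative")
    rng = np.random.default_rng(seed)
    ts0, te0 = table.ts, table.te
    extant = te0 == 0.0
    tables = []
    for _ in range(n_replicates):
        if jitter_sd == 0:
            tables.append(LifespanTable(table.data))
            continue
        te = te0.copy()
        # truncated draws by resampling; extinct species keep te > 0
        resample = ~extant
        while resample.any():
            te[resample] = te0[resample] + rng.normal(
                0, jitter_sd, resample.sum()
            )
            resample = (te <= 0) & ~extant
        te[extant] = 0.0
        ts = ts0.copy()
        resample = np.ones(len(ts0), dtype=bool)
        while resample.any():
            prop = ts0[resample] + rng.normal(0, jitter_sd, resample.sum())
            ts[resample] = prop
            resample = ts <= te
        df = table.data.copy()
        df["ts"], df["te"] = ts, te
        df["extant"] = df["te"] == 0.0
        tables.append(LifespanTable(df[["species_id", "ts", "te"]]))
    return ReplicateSet(tables)


# ---------------------------------------------------------------------------
# rasters and localities


def simulate_elevation_grid(
    shape: str = "disc",
    n_cells: int = 100,
    roughness_sd: float = 0.0,
    base_elevation: float = 100.0,
    cellsize: float = 50.0,
    seed: int | None = None,
) -> tuple[ElevationGrid, dict[str, float]]:
    """Synthetic landmass raster with analytically known geometry.

    Shapes: ``disc`` (radius 0.35 * n_cells), ``square`` (side
    0.7 * n_cells) or ``composite`` (disc plus an offset square island).
    Returns the grid and ground-truth metrics {area, perimeter} in km
    units, computed from the analytic shape, plus the roughness sd used.
    Elevations are a flat base plus iid Gaussian roughness.
    """
    if n_cells < 30:
        raise ValidationError("shape must span at least ~20 cells; raise n_cells")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:n_cells, 0:n_cells]
    cx = cy = (n_cells - 1) / 2.0
    if shape == "disc":
        r = 0.35 * n_cells
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
        truth = {
            "area": np.pi * r**2 * cellsize**2,
            "perimeter": 2 * np.pi * r * cellsize,
        }
    elif shape == "square":
        half = 0.35 * n_cells
        mask = (np.abs(xx - cx) <= half) & (np.abs(yy - cy) <= half)
        side_cells = 2 * half
        truth = {
            "area": side_cells**2 * cellsize**2,
            "perimeter": 4 * side_cells * cellsize,
        }
    elif shape == "composite":
        r = 0.25 * n_cells
        disc = (xx - 0.35 * n_cells) ** 2 + (yy - cy) ** 2 <= r**2
        half = 0.12 * n_cells
        sq = (np.abs(xx - 0.8 * n_cells) <= half) & (np.abs(yy - cy) <= half)
        mask = disc | sq
        truth = {
            "area": (np.pi * r**2 + (2 * half) ** 2) * cellsize**2,
            "perimeter": (2 * np.pi * r + 8 * half) * cellsize,
        }
    else:
        raise ValueError(f"unknown shape {shape!r}")
    if mask.sum() and mask.any(axis=1).sum() < 3:
        raise ValidationError("shape thinner than 3 cells")
    elev = np.full((n_cells, n_cells), base_elevation, dtype=float)
    if roughness_sd > 0:
        elev += rng.normal(0.0, roughness_sd, elev.shape)
    elev[~mask] = np.nan
    grid = ElevationGrid(
        elevation=elev, mask=mask, cellsize=cellsize, xll=0.0, yll=0.0
    )
    truth["roughness_sd"] = roughness_sd
    return grid, truth


def simulate_localities(
    table: LifespanTable,
    grid: ElevationGrid,
    per_lineage_rate: float,
    n_clusters: int = 5,
    cluster_spread: float = 2.0,
    seed: int | None = None,
) -> LocalityTable:
    """Fossil localities from a Poisson sampling process on lineages.

    Each species emits occurrences at ``per_lineage_rate`` events/Myr over
    its lifespan; occurrence ages are uniform within [te, ts].  Sites are
    clustered around ``n_clusters`` random land-cell centres (basin id =
    cluster id), positions in degrees derived from cell coordinates.
    """
    if per_lineage_rate < 0:
        raise ValidationError("per_lineage_rate must be non-negative")
    if grid.n_land == 0:
        raise ValidationError("grid has no land")
    rng = np.random.default_rng(seed)
    land_rows, land_cols = np.nonzero(grid.mask)
    centre_idx = rng.choice(len(land_rows), size=n_clusters, replace=True)
    nrows = grid.shape[0]
    # map cells to pseudo lon/lat: 0.1 degree per cell around (10E, 45N)
    def cell_lonlat(r: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lon = 10.0 + 0.1 * (c - grid.shape[1] / 2)
        lat = 45.0 + 0.1 * (nrows / 2 - r)
        return lon, lat

    rows: list[tuple[str, float, float, float, str]] = []
    k = 0
    land_set = set(zip(land_rows.tolist(), land_cols.tolist()))
    for _, sp in table.data.iterrows():
        span = sp["ts"] - sp["te"]
        n = rng.poisson(per_lineage_rate * span)
        for _ in range(n):
            age = rng.uniform(sp["te"], sp["ts"])
            cl = int(rng.integers(n_clusters))
            r0, c0 = land_rows[centre_idx[cl]], land_cols[centre_idx[cl]]
            # jitter around the centre, resample until on land
            for _try in range(100):
                r = int(round(r0 + rng.normal(0, cluster_spread)))
                c = int(round(c0 + rng.normal(0, cluster_spread)))
                if (r, c) in land_set:
                    break
            else:
                r, c = int(r0), int(c0)
            lon, lat = cell_lonlat(np.array(r), np.array(c))
            k += 1
            rows.append((f"loc{k:06d}", float(lon), float(lat), age, f"basin{cl}"))
    df = pd.DataFrame(
        rows, columns=["locality_id", "lon", "lat", "age", "basin_id"]
    )
    return LocalityTable(df)
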