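"""Core data containers shared across the pipeline.

Time convention: ages are in Ma before present and increase into the past;
the present is 0.  A species' lifespan runs from its origination time ``ts``
back in the past to its extinction time ``te`` closer to the present, so
``ts > te >= 0`` always, and ``te == 0`` encodes an extant species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LifespanTable",
    "ReplicateSet",
    "LocalityTable",
    "ElevationGrid",
    "PredictorSeries",
    "ValidationError",
]

#: grid spacing (Myr) of the predictor / analysis grid
GRID_STEP = 0.1


class ValidationError(ValueError):
    """Raised when an input table violates a container invariant."""


@dataclass(frozen=True)
class LifespanTable:
    """Species lifespans: origination (``ts``) and extinction (``te``) ages.

    Parameters
    ----------
    data : pandas.DataFrame
        Columns ``species_id`` (str), ``ts`` (Ma), ``te`` (Ma).  An
        ``extant`` boolean column is derived (``te == 0``) if absent.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        required = {"species_id", "ts", "te"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"missing columns: {sorted(missing)}")
        df = df.copy()
        df["species_id"] = df["species_id"].astype(str)
        df["ts"] = df["ts"].astype(float)
        df["te"] = df["te"].astype(float)
        if "extant" not in df.columns:
            df["extant"] = df["te"] == 0.0
        df["extant"] = df["extant"].astype(bool)

        bad = df[~(df["ts"] > df["te"])]
        if len(bad):
            names = ", ".join(bad["species_id"].head(10))
            raise ValidationError(
                f"ts must exceed te; violated by rows "
                f"{list(bad.index)} (species: {names})"
            )
        bad = df[df["te"] < 0]
        if len(bad):
            raise ValidationError(
                f"te must be >= 0; violated by rows {list(bad.index)} "
                f"(species: {', '.join(bad['species_id'])})"
            )
        mismatch = df[(df["te"] == 0.0) != df["extant"]]
        if len(mismatch):
            raise ValidationError(
                "extant flag must hold exactly when te == 0; rows "
                f"{list(mismatch.index)}"
            )
        if df["species_id"].duplicated().any():
            dups = df.loc[df["species_id"].duplicated(), "species_id"]
            raise ValidationError(f"duplicate species_id: {sorted(set(dups))}")
        object.__setattr__(self, "data", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.data)

    @property
    def ts(self) -> np.ndarray:
        return self.data["ts"].to_numpy()

    @property
    def te(self) -> np.ndarray:
        return self.data["te"].to_numpy()

    @property
    def species_ids(self) -> list[str]:
        return self.data["species_id"].tolist()

    def lineage_count(self, ages: np.ndarray) -> np.ndarray:
        """Standing richness N(t) at each age, half-open: te <= t < ts."""
        ages = np.asarray(ages, dtype=float)
        ts, te = self.ts, self.te
        return np.count_nonzero(
            (te[None, :] <= ages[:, None]) & (ages[:, None] < ts[None, :]),
            axis=1,
        ).astype(float)


@dataclass(frozen=True)
class ReplicateSet:
    """An ordered set of lifespan tables, one per posterior replicate."""

    tables: Sequence[LifespanTable]
    replicate_ids: Sequence[int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.tables) < 1:
            raise ValidationError("a ReplicateSet needs at least one table")
        ids = self.replicate_ids
        if ids is None:
            ids = list(range(1, len(self.tables) + 1))
        if len(ids) != len(self.tables):
            raise ValidationError("replicate_ids length mismatch")
        ref = set(self.tables[0].species_ids)
        for i, t in enumerate(self.tables[1:], start=1):
            if set(t.species_ids) != ref:
                raise ValidationError(
                    f"replicate {ids[i]} has a different species set"
                )
        object.__setattr__(self, "tables", list(self.tables))
        object.__setattr__(self, "replicate_ids", list(ids))

    def __len__(self) -> int:
        return len(self.tables)

    def __iter__(self) -> Iterator[LifespanTable]:
        return iter(self.tables)

    def __getitem__(self, i: int) -> LifespanTable:
        return self.tables[i]


@dataclass(frozen=True)
class LocalityTable:
    """Fossil localities: id, coordinates (degrees), age (Ma), basin id."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        required = {"locality_id", "lon", "lat", "age", "basin_id"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"missing columns: {sorted(missing)}")
        df = df.copy()
        df["locality_id"] = df["locality_id"].astype(str)
        df["basin_id"] = df["basin_id"].astype(str)
        for c in ("lon", "lat", "age"):
            df[c] = df[c].astype(float)
        if (df["lon"].abs() > 180).any():
            raise ValidationError("longitude outside [-180, 180]")
        if (df["lat"].abs() > 90).any():
            raise ValidationError("latitude outside [-90, 90]")
        if (df["age"] < 0).any():
            raise ValidationError("negative age")
        object.__setattr__(self, "data", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.data)

    def in_slice(self, young: float, old: float) -> pd.DataFrame:
        """Rows with age in the half-open slice [young, old)."""
        m = (self.data["age"] >= young) & (self.data["age"] < old)
        return self.data[m]


@dataclass(frozen=True)
class ElevationGrid:
    """Raster of elevations (metres) with a boolean land mask.

    NODATA cells are sea; the mask is derived, not stored separately.
    ``cellsize`` is the cell edge length in kilometres.
    """

    elevation: np.ndarray
    mask: np.ndarray
    cellsize: float
    xll: float = 0.0
    yll: float = 0.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        elev = np.asarray(self.elevation, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        if elev.shape != mask.shape:
            raise ValidationError("elevation and mask shapes differ")
        if self.cellsize <= 0:
            raise ValidationError("cellsize must be positive")
        object.__setattr__(self, "elevation", elev)
        object.__setattr__(self, "mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation.shape

    @property
    def n_land(self) -> int:
        return int(self.mask.sum())

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing map coordinates (x, y)."""
        nrows = self.elevation.shape[0]
        col = int((x - self.xll) // self.cellsize)
        row = nrows - 1 - int((y - self.yll) // self.cellsize)
        return row, col


@dataclass(frozen=True)
class PredictorSeries:
    """A named predictor on the 0.1 Myr analysis grid.

    ``raw`` holds native units; ``transformed`` holds the
    log10-then-z-scored values the birth-death models consume.
    """

    name: str
    ages: np.ndarray
    raw: np.ndarray
    transformed: np.ndarray | None = None

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        raw = np.asarray(self.raw, dtype=float)
        if ages.ndim != 1 or ages.shape != raw.shape:
            raise ValidationError("ages and raw must be matching 1-D arrays")
        if len(ages) >= 2:
            steps = np.diff(ages)
            if not np.all(steps > 0):
                raise ValidationError("ages must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
                raise ValidationError("ages must be on a constant step")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "raw", raw)
        if self.transformed is not None:
            tr = np.asarray(self.transformed, dtype=float)
            if tr.shape != ages.shape:
                raise ValidationError("transformed shape mismatch")
            object.__setattr__(self, "transformed", tr)

    def __len__(self) -> int:
        return len(self.ages)


def predictor_matrix(
    series: Sequence[PredictorSeries],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack transformed predictor series into (ages, X, names).

    X has one column per predictor, rows aligned on the shared age grid.
    """
    if not series:
        raise ValidationError("no predictor series given")
    ages = series[0].ages
    cols, names = [], []
    for s in series:
        if s.transformed is None:
            raise ValidationError(f"predictor {s.name!r} is not standardized")
        if len(s.ages) != len(ages) or not np.allclose(s.ages, ages):
            raise ValidationError(f"predictor {s.name!r} is on a different grid")
        cols.append(s.transformed)
        names.append(s.name)
    return ages, np.column_stack(cols), names
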