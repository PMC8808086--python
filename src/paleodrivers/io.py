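"""Readers and writers for the tabular and raster formats of the pipeline.

Tables are UTF-8, tab-separated with a header row and '.' decimals.
Rasters use the ESRI ASCII grid dialect (ncols/nrows/xllcorner/yllcorner/
cellsize/NODATA_value header followed by whitespace-separated rows);
NODATA cells are sea, so the land mask is derived from the raster itself.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    ElevationGrid,
    LifespanTable,
    LocalityTable,
    ReplicateSet,
    ValidationError,
)

__all__ = [
    "read_lifespans",
    "write_lifespans",
    "read_predictor_table",
    "write_predictor_table",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_localities",
    "write_localities",
    "RunConfig",
    "FormatError",
]


class FormatError(ValueError):
    """Raised when a file does not match the expected on-disk dialect."""


# ---------------------------------------------------------------------------
# lifespan tables


def read_lifespans(path: str | Path, format: str = "auto") -> ReplicateSet:
    """Read species lifespans from a TSV file.

    Two dialects are accepted: ``wide`` (columns ``species_id``, ``ts``,
    ``te``; a single replicate) and ``long`` (an extra ``replicate``
    column; one table per replicate).  ``auto`` picks by header.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    cols = set(df.columns)
    if format == "auto":
        format = "long" if "replicate" in cols else "wide"
    if format not in ("wide", "long"):
        raise ValueError(f"unknown lifespan format {format!r}")
    required = {"species_id", "ts", "te"}
    if format == "long":
        required = required | {"replicate"}
    missing = required - cols
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")

    if format == "wide":
        return ReplicateSet([LifespanTable(df[["species_id", "ts", "te"]])])

    tables, ids = [], []
    for rid, sub in df.groupby("replicate", sort=True):
        tables.append(LifespanTable(sub[["species_id", "ts", "te"]]))
        ids.append(int(rid))
    return ReplicateSet(tables, ids)


def write_lifespans(replicates: ReplicateSet, path: str | Path) -> None:
    """Write a replicate set in the long dialect (replicate column first)."""
    frames = []
    for rid, table in zip(replicates.replicate_ids, replicates):
        df = table.data[["species_id", "ts", "te"]].copy()
        df.insert(0, "replicate", rid)
        frames.append(df)
    pd.concat(frames).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# predictor tables


def read_predictor_table(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read raw (age, value) pairs; returns (ages, values) sorted by age."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need two columns (age, value)")
    df = df.iloc[:, :2].copy()
    df.columns = ["age", "value"]
    for col in ("age", "value"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            line = int(coerced.index[coerced.isna()][0]) + 2  # header is line 1
            raise FormatError(f"{path}: non-numeric {col} at line {line}")
        df[col] = coerced
    df = df.sort_values("age", kind="stable").reset_index(drop=True)
    if df["age"].duplicated().any():
        dup = df.loc[df["age"].duplicated(), "age"].iloc[0]
        raise ValidationError(f"{path}: duplicated age {dup}")
    return df["age"].to_numpy(), df["value"].to_numpy()


def write_predictor_table(
    ages: np.ndarray, values: np.ndarray, path: str | Path
) -> None:
    pd.DataFrame({"age": ages, "value": values}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# ESRI ASCII grids

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path: str | Path) -> ElevationGrid:
    """Read an ESRI ASCII grid; NODATA cells become sea (mask False)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in _HEADER_KEYS:
        if key not in header:
            raise FormatError(f"{path}: missing header field {key}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    nodata = header.get("nodata_value", -9999.0)
    tokens = " ".join(lines[i:]).split()
    try:
        values = np.array(tokens, dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric raster cell ({exc})") from None
    if values.size != nrows * ncols:
        raise FormatError(
            f"{path}: body has {values.size} values, header implies "
            f"{nrows * ncols}"
        )
    elev = values.reshape(nrows, ncols)
    mask = elev != nodata
    return ElevationGrid(
        elevation=np.where(mask, elev, np.nan),
        mask=mask,
        cellsize=header["cellsize"],
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        nodata=nodata,
    )


def write_ascii_grid(grid: ElevationGrid, path: str | Path) -> None:
    nrows, ncols = grid.shape
    out = np.where(grid.mask, grid.elevation, grid.nodata)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {grid.xll!r}\n")
        fh.write(f"yllcorner {grid.yll!r}\n")
        fh.write(f"cellsize {grid.cellsize!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# locality tables


def read_localities(path: str | Path) -> LocalityTable:
    df = pd.read_csv(path, sep="\t")
    required = {"locality_id", "lon", "lat", "age", "basin_id"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return LocalityTable(df)


def write_localities(table: LocalityTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Configuration shared by the CLI subcommands.

    Window bounds are (young, old) pairs in Ma, ordered and
    non-overlapping.  MCMC defaults are desk-scale; see docs/methods.md.
    """

    windows: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.0, 20.0), (20.0, 40.0), (40.0, 60.0),
                                 (60.0, 80.0), (80.0, 100.0)]
    )
    full_window: tuple[float, float] = (0.0, 100.0)
    generations: int = 200_000
    sample_every: int = 100
    burnin_fraction: float = 0.2
    ess_threshold: float = 100.0
    seed: int = 0
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        prev_old = -np.inf
        for young, old in self.windows:
            if not young < old:
                raise ValidationError(f"window ({young}, {old}) not ordered")
            if young < prev_old:
                raise ValidationError("windows overlap")
            prev_old = old
        if not 0 <= self.burnin_fraction < 1:
            raise ValidationError("burn-in fraction must be in [0, 1)")
        if self.ess_threshold <= 0:
            raise ValidationError("ESS threshold must be positive")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        if "windows" in raw:
            raw["windows"] = [tuple(w) for w in raw["windows"]]
        if "full_window" in raw:
            raw["full_window"] = tuple(raw["full_window"])
        return cls(**raw)
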