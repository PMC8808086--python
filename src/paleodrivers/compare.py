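"""Agreement between BDS baseline rates and MBD-reconstructed rates,
quantified by the mean absolute percentage error (MAPE), plus the
windowed-versus-full comparison table and the per-window effect summary.

The error at a 1 Myr age step is |BDS - MBD| / BDS; the age-level MAPE is
the median of that error across replicates; window and overall MAPEs are
medians of the age-level values in scope (a two-stage median).  Ages where
the BDS rate is zero or negative are undefined (NaN) and excluded from
the medians.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ValidationError
from .mbd import MBDResults

logger = logging.getLogger(__name__)

__all__ = [
    "rate_error",
    "mape_by_age",
    "MAPEReport",
    "build_mape_report",
    "windowed_vs_full",
    "effect_summary",
    "concatenate_windowed_rates",
]


def rate_error(bds_rate, mbd_rate):
    """|bds - mbd| / bds, elementwise; NaN where the BDS rate is <= 0."""
    bds_rate = np.asarray(bds_rate, dtype=float)
    mbd_rate = np.asarray(mbd_rate, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        err = np.abs(bds_rate - mbd_rate) / bds_rate
    bad = ~(bds_rate > 0)
    if np.any(bad):
        logger.info("%d age step(s) with non-positive BDS rate excluded",
                    int(np.sum(bad)))
    err = np.where(bad, np.nan, err)
    return err if err.ndim else float(err)


def mape_by_age(errors: np.ndarray) -> np.ndarray:
    """Median error across replicates at each age (NaNs ignored).

    ``errors`` has shape (n_replicates, n_ages); even replicate counts use
    the midpoint of the two central values.
    """
    errors = np.atleast_2d(np.asarray(errors, dtype=float))
    with np.errstate(invalid="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmedian(errors, axis=0)


@dataclass(frozen=True)
class MAPEReport:
    """Age-level MAPEs per rate on a common 1 Myr grid.

    ``mode`` tags whether the MBD curves came from the windowed or the
    full-frame fit.
    """

    ages: np.ndarray
    age_mape: dict  # rate name -> (n_ages,) age-level medians
    mode: str = "windowed"

    def window_value(self, rate: str, window: tuple[float, float]) -> float:
        a, b = window
        vals = self.age_mape[rate][(self.ages >= a) & (self.ages < b)]
        vals = vals[~np.isnan(vals)]
        return float(np.median(vals)) if vals.size else float("nan")

    def overall(self, rate: str) -> float:
        vals = self.age_mape[rate]
        vals = vals[~np.isnan(vals)]
        return float(np.median(vals)) if vals.size else float("nan")

    def to_frame(self) -> pd.DataFrame:
        cols = {"age": self.ages}
        cols.update({f"mape_{k}": v for k, v in self.age_mape.items()})
        return pd.DataFrame(cols)


def _curve_on_grid(df: pd.DataFrame, rate: str, ages: np.ndarray) -> np.ndarray:
    sub = df[df["rate"] == rate]
    if len(sub) != len(ages) or not np.allclose(sub["age"].to_numpy(), ages):
        raise ValidationError("rate curve is not on the expected age grid")
    return sub["median"].to_numpy()


def build_mape_report(
    bds_rates: pd.DataFrame,
    mbd_replicate_rates: Sequence[pd.DataFrame],
    mode: str = "windowed",
) -> MAPEReport:
    """Replicate-matched MBD median curves against the pooled BDS median.

    All inputs are long tables (age, rate, median, ...) on the same
    1 Myr grid, as produced by ``BDSResults.marginal_rates`` and
    ``MBDResults.reconstruct_rates``.
    """
    ages = np.unique(bds_rates["age"].to_numpy())
    out = {}
    for rate in ("lambda", "mu"):
        b = _curve_on_grid(bds_rates, rate, ages)
        errs = np.vstack([
            rate_error(b, _curve_on_grid(m, rate, ages))
            for m in mbd_replicate_rates
        ])
        out[rate] = mape_by_age(errs)
    return MAPEReport(ages=ages, age_mape=out, mode=mode)


def windowed_vs_full(
    report_windowed: MAPEReport,
    report_full: MAPEReport,
    windows: Sequence[tuple[float, float]],
) -> pd.DataFrame:
    """Side-by-side per-window MAPEs for the two fitting modes.

    The full-frame values are obtained by re-slicing its age-level errors
    into the same windows.  Rows: window x rate, plus a 'total' row per
    rate; the ``winner`` column names the mode with the smaller MAPE.
    """
    if len(report_windowed.ages) != len(report_full.ages) or not np.allclose(
        report_windowed.ages, report_full.ages
    ):
        raise ValidationError("the two reports are on different age grids")
    rows = []
    scopes = [("total", None)] + [(f"{a:g}-{b:g}", (a, b)) for a, b in windows]
    for rate in ("lambda", "mu"):
        for label, win in scopes:
            mw = (
                report_windowed.overall(rate)
                if win is None
                else report_windowed.window_value(rate, win)
            )
            mf = (
                report_full.overall(rate)
                if win is None
                else report_full.window_value(rate, win)
            )
            if np.isnan(mw) or np.isnan(mf):
                winner = "undefined"
            elif mw < mf:
                winner = "windowed"
            elif mf < mw:
                winner = "full"
            else:
                winner = "tie"
            rows.append((label, rate, mw, mf, winner))
    return pd.DataFrame(
        rows, columns=["window", "rate", "mape_windowed", "mape_full", "winner"]
    )


def effect_summary(
    results_per_window: Sequence[MBDResults],
    windows: Sequence[tuple[float, float]],
) -> pd.DataFrame:
    """Long effect table: window, rate, predictor, mean_weight,
    mean_effect, significant — one row per window x predictor x rate.

    Effect sizes are reported unclipped; significance uses the strict
    mean-weight > 0.5 rule.
    """
    if len(results_per_window) != len(windows):
        raise ValidationError("need one result per window")
    names_ref = None
    frames = []
    for res, (a, b) in zip(results_per_window, windows):
        if names_ref is None:
            names_ref = list(res.model.names)
        elif list(res.model.names) != names_ref:
            raise ValidationError("predictor sets differ across windows")
        ss = res.shrinkage_summary()
        ss.insert(0, "window", f"{a:g}-{b:g}")
        frames.append(ss)
    return pd.concat(frames, ignore_index=True)


def concatenate_windowed_rates(
    results_per_window: Sequence[MBDResults],
    replicate: int,
    grid_step: float = 1.0,
) -> pd.DataFrame:
    """Stitch one replicate's per-window rate curves into a single long
    table covering all windows (ages where the replicate failed a
    window's ESS filter are NaN)."""
    frames = []
    for res in results_per_window:
        if replicate in res.included:
            frames.append(res.reconstruct_rates(grid_step, replicate=replicate))
        else:
            a, b = res.model.window
            grid = np.arange(a + grid_step / 2, b, grid_step)
            for rate in ("lambda", "mu"):
                frames.append(pd.DataFrame({
                    "age": grid, "rate": rate,
                    "median": np.nan, "lo": np.nan, "hi": np.nan,
                }))
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["rate", "age"], kind="stable").reset_index(drop=True)
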