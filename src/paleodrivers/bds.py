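"""Birth-death model with shifts (BDS): piecewise-constant speciation and
extinction rates whose number and ages of shift points are inferred by
reversible-jump MCMC from species lifespans.

Given lifespans (ts_i, te_i) and a rate model lambda(t), mu(t), the
log-likelihood over a window [a, b) is

    log L = sum_births log lambda(ts_i) + sum_deaths log mu(te_i)
            - int_a^b N(t) * (lambda(t) + mu(t)) dt

with N(t) the standing lineage count.  Events clipped at the window edges
contribute exposure only.  Speciation and extinction have independent
shift-point structures, and because the likelihood factorizes the two
sides are sampled by independent RJ chains.

Priors: shift count ~ Poisson(0.5) per rate; rate levels ~ Gamma(2, 2)
(events/Myr); shift ages ordered-uniform over the window.  Proposal
scales are tuned during burn-in only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import LifespanTable, ValidationError

__all__ = [
    "RateModel",
    "BDSPriors",
    "bd_loglik",
    "BirthDeathShiftsModel",
    "BDSResults",
    "marginal_rates",
]


@dataclass(frozen=True)
class RateModel:
    """Piecewise-constant rate functions lambda(t), mu(t).

    Shift ages are ascending (toward the past); level j applies between
    shift j-1 and shift j (the youngest interval comes first).  Speciation
    and extinction have independent shift structures.
    """

    lambda_shifts: tuple[float, ...]
    lambda_levels: tuple[float, ...]
    mu_shifts: tuple[float, ...]
    mu_levels: tuple[float, ...]

    def __post_init__(self) -> None:
        for shifts, levels, nm in (
            (self.lambda_shifts, self.lambda_levels, "lambda"),
            (self.mu_shifts, self.mu_levels, "mu"),
        ):
            if len(levels) != len(shifts) + 1:
                raise ValidationError(f"{nm}: need len(levels) == len(shifts)+1")
            if any(np.diff(shifts) <= 0):
                raise ValidationError(f"{nm}: shift ages must be ascending")
            if any(level < 0 for level in levels):
                raise ValidationError(f"{nm}: negative rate level")

    @classmethod
    def constant(cls, lam: float, mu: float) -> "RateModel":
        return cls((), (lam,), (), (mu,))

    def lambda_at(self, ages: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.lambda_shifts, ages, side="right")
        return np.asarray(self.lambda_levels, float)[idx]

    def mu_at(self, ages: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.mu_shifts, ages, side="right")
        return np.asarray(self.mu_levels, float)[idx]


@dataclass(frozen=True)
class BDSPriors:
    poisson_nu: float = 0.5      # mean shift count per rate
    gamma_shape: float = 2.0     # rate-level prior Gamma(shape, rate)
    gamma_rate: float = 2.0


# ---------------------------------------------------------------------------
# likelihood machinery


def _clip_events(
    table: LifespanTable, window: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(birth ages, death ages, clipped starts, clipped ends) inside [a, b)."""
    a, b = window
    ts, te = table.ts, table.te
    keep = (te < b) & (ts > a)
    ts, te = ts[keep], te[keep]
    births = ts[(ts > a) & (ts < b)]
    deaths = te[(te > a) & (te < b)]
    return births, deaths, np.minimum(ts, b), np.maximum(te, a)


def _exposure_knots(
    starts: np.ndarray, ends: np.ndarray, window: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative lineage-time C(t) = int_a^t N(s) ds as (knots, values)."""
    a, b = window
    knots = np.unique(np.concatenate(([a, b], starts, ends)))
    mid = 0.5 * (knots[:-1] + knots[1:])
    counts = np.count_nonzero(
        (ends[None, :] <= mid[:, None]) & (mid[:, None] < starts[None, :]),
        axis=1,
    ).astype(float)
    cum = np.concatenate(([0.0], np.cumsum(counts * np.diff(knots))))
    return knots, cum


class _SideData:
    """Per-rate sufficient statistics for the piecewise-constant likelihood."""

    def __init__(
        self,
        event_ages: np.ndarray,
        knots: np.ndarray,
        cum: np.ndarray,
        window: tuple[float, float],
    ) -> None:
        self.events = np.sort(event_ages)
        self.knots = knots
        self.cum = cum
        self.window = window

    def exposure(self, t1: float, t2: float) -> float:
        c1, c2 = np.interp([t1, t2], self.knots, self.cum)
        return float(c2 - c1)

    def loglik(self, shifts: np.ndarray, levels: np.ndarray) -> float:
        a, b = self.window
        bounds = np.concatenate(([a], shifts, [b]))
        counts = np.diff(np.searchsorted(self.events, bounds, side="left"))
        expo = np.diff(np.interp(bounds, self.knots, self.cum))
        if np.any((levels <= 0) & (counts > 0)):
            return -math.inf
        with np.errstate(divide="ignore"):
            ll = np.where(counts > 0, counts * np.log(levels), 0.0)
        return float(np.sum(ll) - np.sum(levels * expo))


def bd_loglik(
    table: LifespanTable, model: RateModel, window: tuple[float, float]
) -> float:
    """Exact log-likelihood of a piecewise-constant rate model."""
    a, b = window
    if not a < b:
        raise ValidationError("window must satisfy a < b")
    births, deaths, starts, ends = _clip_events(table, window)
    knots, cum = _exposure_knots(starts, ends, window)
    lam_side = _SideData(births, knots, cum, window)
    mu_side = _SideData(deaths, knots, cum, window)
    ll = lam_side.loglik(
        np.asarray(model.lambda_shifts, float), np.asarray(model.lambda_levels, float)
    )
    ll += mu_side.loglik(
        np.asarray(model.mu_shifts, float), np.asarray(model.mu_levels, float)
    )
    return ll


# ---------------------------------------------------------------------------
# reversible-jump sampler (one rate side)


def _rj_side_chain(
    side: _SideData,
    priors: BDSPriors,
    generations: int,
    sample_every: int,
    burnin: int,
    rng: np.random.Generator,
    rate_grid: np.ndarray,
    kmax: int = 50,
    prior_only: bool = False,
) -> dict[str, object]:
    """RJ-MCMC over (shift ages, levels) for one rate.

    Moves: level multiplier, shift slide, birth of a shift (new age
    uniform; the older sub-interval draws a fresh level from the prior),
    death of a shift (the merged interval keeps the younger level).
    With the birth-level drawn from its prior, the acceptance ratio for a
    birth is L-ratio * nu / (k+1) and for a death L-ratio * k / nu.
    """
    a, b = side.window
    span = b - a
    nu = priors.poisson_nu
    g_shape, g_rate = priors.gamma_shape, priors.gamma_rate

    shifts = np.empty(0)
    levels = np.array([max(len(side.events), 1.0) / max(side.exposure(a, b), 1e-9)])
    if prior_only:
        loglik = lambda s, l: 0.0  # noqa: E731 - sampling the prior
    else:
        loglik = side.loglik
    ll = loglik(shifts, levels)
    if not np.isfinite(ll):
        levels = np.array([1.0])
        ll = loglik(shifts, levels)
        if not np.isfinite(ll):
            raise RuntimeError("no finite-likelihood starting state found")

    def log_prior_level(h: float) -> float:
        return (g_shape - 1) * math.log(h) - g_rate * h

    delta_level = 0.8
    delta_slide = max(span / 10.0, 1e-6)
    acc_level = try_level = acc_slide = try_slide = 0

    n_samples = (generations - burnin) // sample_every
    out_k = np.empty(n_samples, dtype=np.int64)
    out_ll = np.empty(n_samples)
    out_rates = np.empty((n_samples, len(rate_grid)))
    out_shifts: list[np.ndarray] = []
    s_idx = 0

    for it in range(generations):
        k = len(shifts)
        u_move = rng.uniform()
        if u_move < 0.35:  # level multiplier
            j = int(rng.integers(k + 1))
            h = levels[j]
            h_new = h * math.exp(delta_level * (rng.uniform() - 0.5))
            new_levels = levels.copy()
            new_levels[j] = h_new
            ll_new = loglik(shifts, new_levels)
            log_alpha = (
                ll_new - ll
                + log_prior_level(h_new) - log_prior_level(h)
                + math.log(h_new / h)  # Hastings for the multiplier
            )
            try_level += 1
            if math.log(rng.uniform()) < log_alpha:
                levels, ll = new_levels, ll_new
                acc_level += 1
        elif u_move < 0.55:  # slide a shift
            if k > 0:
                i = int(rng.integers(k))
                lo = shifts[i - 1] if i > 0 else a
                hi = shifts[i + 1] if i < k - 1 else b
                s_new = shifts[i] + delta_slide * (rng.uniform() - 0.5) * 2
                try_slide += 1
                if lo < s_new < hi:
                    new_shifts = shifts.copy()
                    new_shifts[i] = s_new
                    ll_new = loglik(new_shifts, levels)
                    if math.log(rng.uniform()) < ll_new - ll:
                        shifts, ll = new_shifts, ll_new
                        acc_slide += 1
        elif u_move < 0.775:  # birth of a shift
            if k < kmax:
                t_star = rng.uniform(a, b)
                h_star = rng.gamma(g_shape, 1.0 / g_rate)
                j = int(np.searchsorted(shifts, t_star))
                new_shifts = np.insert(shifts, j, t_star)
                # younger part keeps the old level; older part gets h_star
                new_levels = np.insert(levels, j + 1, h_star)
                ll_new = loglik(new_shifts, new_levels)
                log_alpha = ll_new - ll + math.log(nu) - math.log(k + 1)
                if math.log(rng.uniform()) < log_alpha:
                    shifts, levels, ll = new_shifts, new_levels, ll_new
        else:  # death of a shift
            if k > 0:
                i = int(rng.integers(k))
                new_shifts = np.delete(shifts, i)
                # merged interval keeps the younger level (index i)
                new_levels = np.delete(levels, i + 1)
                ll_new = loglik(new_shifts, new_levels)
                log_alpha = ll_new - ll + math.log(k) - math.log(nu)
                if math.log(rng.uniform()) < log_alpha:
                    shifts, levels, ll = new_shifts, new_levels, ll_new

        # proposal-scale tuning, burn-in only
        if it < burnin and (it + 1) % 200 == 0:
            if try_level:
                rate = acc_level / try_level
                delta_level *= 1.15 if rate > 0.35 else (1 / 1.15 if rate < 0.2 else 1.0)
            if try_slide:
                rate = acc_slide / try_slide
                delta_slide *= 1.15 if rate > 0.35 else (1 / 1.15 if rate < 0.2 else 1.0)
                delta_slide = min(delta_slide, span)
            acc_level = try_level = acc_slide = try_slide = 0

        if it >= burnin and (it - burnin) % sample_every == 0 and s_idx < n_samples:
            out_k[s_idx] = len(shifts)
            out_ll[s_idx] = ll
            idx = np.searchsorted(shifts, rate_grid, side="right")
            out_rates[s_idx] = levels[idx]
            out_shifts.append(shifts.copy())
            s_idx += 1

    return {
        "shift_count": out_k[:s_idx],
        "loglik": out_ll[:s_idx],
        "rates": out_rates[:s_idx],
        "shift_ages": out_shifts,
    }


# ---------------------------------------------------------------------------
# percentile summaries


def marginal_rates(
    rate_samples: np.ndarray, ages: np.ndarray, min_samples: int = 50
) -> pd.DataFrame:
    """Pointwise median and 95% credible band of sampled rate curves."""
    if rate_samples.shape[0] < min_samples:
        raise ValidationError(
            f"need at least {min_samples} retained samples, "
            f"got {rate_samples.shape[0]}"
        )
    lo, med, hi = np.percentile(rate_samples, [2.5, 50.0, 97.5], axis=0)
    return pd.DataFrame({"age": ages, "median": med, "lo": lo, "hi": hi})


# ---------------------------------------------------------------------------
# model / results objects


class BirthDeathShiftsModel:
    """BDS model bound to one lifespan table and an analysis window.

    Parameters
    ----------
    table : LifespanTable
    window : (young, old) in Ma; defaults to [0, max(ts)) so that founders
        entering at the oldest age are exposure-only.
    priors : BDSPriors
    """

    def __init__(
        self,
        table: LifespanTable,
        window: tuple[float, float] | None = None,
        priors: BDSPriors = BDSPriors(),
    ) -> None:
        self.table = table
        if window is None:
            window = (0.0, float(table.ts.max()))
        if not window[0] < window[1]:
            raise ValidationError("window must satisfy young < old")
        self.window = window
        self.priors = priors
        births, deaths, starts, ends = _clip_events(table, window)
        knots, cum = _exposure_knots(starts, ends, window)
        self._lam_side = _SideData(births, knots, cum, window)
        self._mu_side = _SideData(deaths, knots, cum, window)

    def loglik(self, model: RateModel) -> float:
        return bd_loglik(self.table, model, self.window)

    def fit(
        self,
        generations: int = 100_000,
        sample_every: int = 50,
        burnin_fraction: float = 0.2,
        seed: int | None = None,
        grid_step: float = 1.0,
        prior_only: bool = False,
    ) -> "BDSResults":
        """Run the RJ-MCMC and return posterior summaries.

        ``prior_only`` replaces the likelihood by a constant, so the chain
        samples the prior — used to validate the reversible-jump moves.
        """
        if generations < 10 * sample_every:
            raise ValidationError("generations must be >= 10 * sample_every")
        burnin = int(burnin_fraction * generations)
        a, b = self.window
        ages = np.arange(a + grid_step / 2, b, grid_step)
        ss = np.random.SeedSequence(seed)
        rng_lam, rng_mu = (np.random.default_rng(s) for s in ss.spawn(2))
        lam = _rj_side_chain(
            self._lam_side, self.priors, generations, sample_every, burnin,
            rng_lam, ages, prior_only=prior_only,
        )
        mu = _rj_side_chain(
            self._mu_side, self.priors, generations, sample_every, burnin,
            rng_mu, ages, prior_only=prior_only,
        )
        return BDSResults(self, ages, lam, mu)


@dataclass
class BDSResults:
    """Posterior of a BDS fit: retained samples and rate summaries."""

    model: BirthDeathShiftsModel
    grid_ages: np.ndarray
    lam: dict = field(repr=False, default_factory=dict)
    mu: dict = field(repr=False, default_factory=dict)

    @property
    def lambda_shift_counts(self) -> np.ndarray:
        return self.lam["shift_count"]

    @property
    def mu_shift_counts(self) -> np.ndarray:
        return self.mu["shift_count"]

    def modal_shift_count(self, rate: str = "lambda") -> int:
        counts = self.lam if rate == "lambda" else self.mu
        vals, freq = np.unique(counts["shift_count"], return_counts=True)
        return int(vals[np.argmax(freq)])

    def marginal_rates(self) -> pd.DataFrame:
        """Long table: age, rate ('lambda'|'mu'), median, lo, hi."""
        frames = []
        for name, side in (("lambda", self.lam), ("mu", self.mu)):
            df = marginal_rates(side["rates"], self.grid_ages)
            df.insert(1, "rate", name)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def shift_age_samples(self, rate: str = "lambda") -> np.ndarray:
        """All sampled shift ages pooled across retained generations."""
        side = self.lam if rate == "lambda" else self.mu
        ages = side["shift_ages"]
        return np.concatenate(ages) if ages else np.empty(0)

    def rate_credible_interval(
        self, rate: str = "lambda"
    ) -> tuple[float, float]:
        """95% CI of the time-averaged rate (single-interval summary)."""
        side = self.lam if rate == "lambda" else self.mu
        means = side["rates"].mean(axis=1)
        lo, hi = np.percentile(means, [2.5, 97.5])
        return float(lo), float(hi)

    def summary(self) -> str:
        lines = [
            "Birth-death-with-shifts posterior",
            f"  window: [{self.model.window[0]:g}, {self.model.window[1]:g}) Ma",
            f"  retained samples: {len(self.lam['shift_count'])}",
            f"  modal shift count: lambda={self.modal_shift_count('lambda')}, "
            f"mu={self.modal_shift_count('mu')}",
        ]
        mr = self.marginal_rates()
        for name in ("lambda", "mu"):
            sub = mr[mr["rate"] == name]
            lines.append(
                f"  {name}: median over grid {sub['median'].median():.4f} "
                f"events/Myr (95% band {sub['lo'].min():.4f}-{sub['hi'].max():.4f})"
            )
        return "\n".join(lines)

    def plot_rates(self, ax=None):
        """Quick-look rate-through-time plot (median + 95% band)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        mr = self.marginal_rates()
        for name, color in (("lambda", "C0"), ("mu", "C3")):
            sub = mr[mr["rate"] == name]
            ax.plot(sub["age"], sub["median"], color=color, label=name)
            ax.fill_between(sub["age"], sub["lo"], sub["hi"], color=color, alpha=0.2)
        ax.set_xlabel("age (Ma)")
        ax.set_ylabel("rate (events/Myr)")
        ax.invert_xaxis()
        ax.legend()
        return ax
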