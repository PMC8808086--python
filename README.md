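# paleodrivers

Tools for asking *what drove speciation and extinction through deep time* —
and whether the answer changes when you look at shorter time windows.

The package targets the situation of a densely sampled fossil record (its
motivating case is a continental fauna of freshwater gastropods spanning
the last 100 Myr) where per-species origination and extinction times
(`ts`, `te`, in Ma) are available, together with candidate biotic and
abiotic predictor time series: standing diversity, temperature,
precipitation, continental area, elevation, basin geometry, terrain
ruggedness (TRI), geographic distance among fossil sites, and a tectonic
complexity index (TCI) that combines coastline shape with relief.

## Models

**Birth–death with shifts (BDS).** Piecewise-constant speciation and
extinction rates λ(t), μ(t); the number and ages of rate shifts are
inferred by reversible-jump MCMC. The log-likelihood of lifespans over a
window [a, b) is

    log L = Σ_births log λ(ts_i) + Σ_deaths log μ(te_i)
            − ∫_a^b N(t) (λ(t) + μ(t)) dt

with N(t) the standing lineage count. This is the descriptive baseline:
what the rates did, with no explanation attached.

**Multivariate birth–death (MBD).** Rates respond exponentially to
standardized predictors x_j(t):

    λ(t) = λ0 · exp(Σ_j Gλ_j x_j(t)),   μ(t) = μ0 · exp(Σ_j Gμ_j x_j(t))

Coefficients carry horseshoe shrinkage priors; support for predictor j is
read off the shrinkage weight ω_j = 1 − 1/(1 + l_j²) (l_j the local
scale), with mean ω across replicates > 0.5 flagging a significant
effect. Fits are replicated over jittered lifespan tables to propagate
age uncertainty, and replicates with effective sample sizes below 100 are
re-run with longer chains, then excluded if still unconverged.

**Windowed vs. full-frame comparison.** The MBD model is fitted either
once over the whole frame or independently inside sequential 20 Myr
windows. Agreement of each reconstruction with the BDS baseline is scored
by MAPE: per 1 Myr step, median over replicates of |BDS − MBD| / BDS,
then the median over steps in scope.

A synthetic-data module generates every input with known truth: lifespans
from a covariate-driven birth–death process (budding speciation, exact
thinning), replicate jitter, predictor trajectories (constant / linear /
Ornstein–Uhlenbeck / step), rasterized landmasses with analytic geometry,
and clustered fossil localities.

## Worked example

```python
import numpy as np
import paleodrivers as pdv

# one OU-shaped predictor, standardized on the 0.1 Myr analysis grid
raw = pdv.simulate_predictor_series(
    pdv.PredictorTruth(kind="ou", reversion=0.05), 105.0, seed=100, name="x1"
)
x1 = pdv.standardize_series(raw.ages, raw.raw, 105.0, name="x1",
                            log_transform=False)

# lifespans whose speciation rate follows x1 (G_lambda = 0.8)
truth = pdv.SimulationTruth(lambda0=0.025, mu0=0.02, g_lambda=(0.8,),
                            g_mu=(0.0,), t_start=105.0, n_founders=80,
                            seed=42)
table = pdv.simulate_bd_lifespans(truth, [x1])
reps = pdv.perturb_replicates(table, jitter_sd=0.2, n_replicates=5, seed=7)

res = pdv.MultivariateBirthDeath(reps, [x1], window=(0.0, 100.0)).fit(
    settings=pdv.MBDSettings(generations=50_000, sample_every=50), seed=5
)
print(res.shrinkage_summary().to_string(index=False))
```

Output:

```
  rate predictor  mean_weight  mean_effect  significant
lambda        x1     0.531448     0.823082         True
    mu        x1     0.325101    -0.146668        False
```

The active predictor is recovered on the speciation side (mean shrinkage
weight 0.53 > 0.5, posterior mean effect 0.82 vs. a true 0.8), while the
extinction side — simulated with no effect — stays shrunk (0.33 < 0.5).

A BDS baseline for the same data:

```python
bds = pdv.BirthDeathShiftsModel(reps[0], (0.0, 100.0)).fit(
    generations=40_000, sample_every=25, seed=11
)
print(bds.summary())
```

```
Birth-death-with-shifts posterior
  window: [0, 100) Ma
  retained samples: 1280
  modal shift count: lambda=3, mu=0
  lambda: median over grid 0.0170 events/Myr (95% band 0.0119-0.3862)
  mu: median over grid 0.0205 events/Myr (95% band 0.0176-0.0236)
```

The shift model sees the speciation-rate variation that x1 induced
(modal shift count 3) but flat extinction, matching the simulation.

The command-line interface mirrors the pipeline stages (`paleodrivers
simulate | predictors | bds | mbd | compare`); each subcommand takes
`--config` (TOML), `--seed` and `--out-dir`, and prints the seed it used.

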