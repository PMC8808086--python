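"""Window clipping, MBD likelihood closed forms, horseshoe machinery and
small-scale posterior behaviour."""

import math

import numpy as np
import pandas as pd
import pytest

import paleodrivers as pdv
from paleodrivers._mbd_kernel import run_chain
from paleodrivers.containers import PredictorSeries, ValidationError
from paleodrivers.simulate import SimulationTruth


def single_species(ts, te):
    return pdv.LifespanTable(pd.DataFrame({
        "species_id": ["a"], "ts": [ts], "te": [te],
    }))


def const_predictor(value=1.0, t_max=100.0, name="x"):
    ages = np.round(np.arange(0, t_max + 0.05, 0.1), 9)
    vals = np.full_like(ages, value)
    return PredictorSeries(name, ages, vals, transformed=vals)


class TestClipToWindow:
    def test_ts_clipped_keeps_death_event(self):
        df = pdv.clip_to_window(single_species(30.0, 5.0), (0.0, 20.0))
        row = df.iloc[0]
        assert row["ts_clip"] == 20.0 and row["te_clip"] == 5.0
        assert not row["birth_event"] and row["death_event"]

    def test_fully_inside_keeps_both_events(self):
        df = pdv.clip_to_window(single_species(15.0, 12.0), (0.0, 20.0))
        row = df.iloc[0]
        assert row["birth_event"] and row["death_event"]
        assert row["ts_clip"] == 15.0 and row["te_clip"] == 12.0

    def test_outside_window_dropped(self):
        df = pdv.clip_to_window(single_species(90.0, 70.0), (0.0, 20.0))
        assert len(df) == 0

    def test_extant_in_window_no_death_event(self):
        df = pdv.clip_to_window(single_species(15.0, 0.0), (0.0, 20.0))
        assert not df.iloc[0]["death_event"]

    def test_te_clipped_drops_death_event(self):
        df = pdv.clip_to_window(single_species(50.0, 10.0), (20.0, 60.0))
        row = df.iloc[0]
        assert row["te_clip"] == 20.0
        assert row["birth_event"] and not row["death_event"]


class TestMBDLoglik:
    def test_reduces_to_constant_bd_when_g_zero(self, three_species):
        s = const_predictor()
        st = pdv.MBDState(0.2, 0.1, (0.0,), (0.0,))
        ll = pdv.mbd_loglik(
            three_species, st, s.ages, s.transformed[:, None], (0.0, 100.0)
        )
        bd = pdv.bd_loglik(
            three_species, pdv.RateModel.constant(0.2, 0.1), (0.0, 100.0)
        )
        assert ll == pytest.approx(bd, abs=1e-9)

    def test_closed_form_with_unit_predictor(self):
        s = const_predictor()
        st = pdv.MBDState(0.1, 0.1, (1.0,), (0.0,))
        ll = pdv.mbd_loglik(
            single_species(10.0, 5.0), st, s.ages,
            s.transformed[:, None], (0.0, 100.0),
        )
        lam = 0.1 * math.e
        assert ll == pytest.approx(
            math.log(lam) + math.log(0.1) - (lam + 0.1) * 5, abs=1e-9
        )

    def test_link_identity_scaling_x_and_g(self, three_species):
        s1 = const_predictor(1.0)
        s2 = const_predictor(2.0)
        ll1 = pdv.mbd_loglik(
            three_species, pdv.MBDState(0.1, 0.1, (0.8,), (0.4,)),
            s1.ages, s1.transformed[:, None], (0.0, 100.0),
        )
        ll2 = pdv.mbd_loglik(
            three_species, pdv.MBDState(0.1, 0.1, (0.4,), (0.2,)),
            s2.ages, s2.transformed[:, None], (0.0, 100.0),
        )
        assert ll1 == pytest.approx(ll2, rel=1e-12)

    def test_overflow_returns_minus_inf(self):
        s = const_predictor(1.0)
        st = pdv.MBDState(1.0, 1.0, (1000.0,), (0.0,))
        ll = pdv.mbd_loglik(
            single_species(10.0, 5.0), st, s.ages,
            s.transformed[:, None], (0.0, 100.0),
        )
        assert ll == -np.inf


class TestShrinkageWeight:
    def test_formula_fixed_points(self):
        assert pdv.shrinkage_weight(1.0) == pytest.approx(0.5)
        assert pdv.shrinkage_weight(3.0) == pytest.approx(0.9)
        assert pdv.shrinkage_weight(1e-8) == pytest.approx(0.0, abs=1e-9)

    def test_invalid_scale(self):
        with pytest.raises(ValidationError):
            pdv.shrinkage_weight(0.0)


class TestHorseshoePrior:
    def test_gibbs_chain_alone_samples_half_cauchy_local_scales(self):
        """Run the kernel with no data: the chain then samples the joint
        prior, and the local-scale marginals must match half-Cauchy(0,1)
        quantiles within Monte-Carlo error."""
        p = 2
        n_iter = 60_000
        rng = np.random.default_rng(8)
        X = np.zeros((1, p))
        N_dt = np.zeros(1)
        tr, pa, om = run_chain(
            X, N_dt, np.zeros(p), 0, np.zeros(p), 0,
            1.1, 1.0, n_iter, 0, 5,
            rng.standard_normal((n_iter, 2 + 2 * p)),
            rng.uniform(size=(n_iter, 2 + 2 * p)),
            rng.standard_exponential((n_iter, 4 * p + 2)),
            rng.gamma((p + 1) / 2, 1.0, size=(n_iter, 2)),
            rng.standard_normal((n_iter, 2 * p)),
            rng.uniform(size=(n_iter, 2 * p)),
        )
        # For l ~ half-Cauchy(0,1), omega = l^2/(1+l^2) = sin^2(theta)
        # with theta ~ U(0, pi/2), so the quantile function is
        # sin^2(q * pi/2).
        w = om[:, 0]
        assert np.median(w) == pytest.approx(0.5, abs=0.03)
        assert np.quantile(w, 0.25) == pytest.approx(
            math.sin(math.pi / 8) ** 2, abs=0.03
        )
        assert np.quantile(w, 0.75) == pytest.approx(
            math.sin(3 * math.pi / 8) ** 2, abs=0.03
        )


@pytest.fixture(scope="module")
def mbd_dataset(request):
    """~500 species driven by one active predictor, 3 jittered replicates."""
    series = []
    for j in range(3):
        raw = pdv.simulate_predictor_series(
            pdv.PredictorTruth(kind="ou", reversion=0.05),
            100.0, seed=100 + j, name=f"x{j + 1}",
        )
        series.append(pdv.standardize_series(
            raw.ages, raw.raw, 100.0, name=raw.name, log_transform=False
        ))
    truth = SimulationTruth(
        lambda0=0.03, mu0=0.025, g_lambda=(0.8, 0.0, 0.0),
        g_mu=(0.0, 0.0, 0.0), t_start=100.0, n_founders=100, seed=42,
    )
    tab = pdv.simulate_bd_lifespans(truth, series)
    reps = pdv.perturb_replicates(tab, 0.2, 3, seed=7)
    return reps, series


class TestFit:
    def test_same_seed_identical_summaries(self, mbd_dataset):
        reps, series = mbd_dataset
        settings = pdv.MBDSettings(generations=8_000, sample_every=20)
        fit = lambda: pdv.run_mbd(  # noqa: E731
            reps, series, (0.0, 100.0), settings=settings, seed=5
        )
        a, b = fit(), fit()
        pd.testing.assert_frame_equal(
            a.shrinkage_summary(), b.shrinkage_summary()
        )
        pd.testing.assert_frame_equal(a.ess_report, b.ess_report)

    def test_active_predictor_detected_single_seed(self, mbd_dataset):
        reps, series = mbd_dataset
        settings = pdv.MBDSettings(generations=50_000, sample_every=50)
        res = pdv.run_mbd(reps, series, (0.0, 100.0), settings=settings, seed=5)
        ss = res.shrinkage_summary()
        lam = ss[ss["rate"] == "lambda"].set_index("predictor")
        assert lam.loc["x1", "mean_weight"] > 0.5
        assert lam.loc["x1", "significant"]
        assert lam.loc["x2", "mean_weight"] < 0.5
        # effect sign and rough magnitude
        assert 0.3 < lam.loc["x1", "mean_effect"] < 1.3

    def test_standardization_shift_neutrality(self, mbd_dataset):
        reps, _ = mbd_dataset
        rng = np.random.default_rng(0)
        ages = np.arange(0.0, 101.0, 5.0)
        vals = rng.uniform(5, 10, len(ages))
        s1 = pdv.standardize_series(ages, vals, 100.0, name="x",
                                    log_transform=False)
        s2 = pdv.standardize_series(ages, vals + 1000.0, 100.0, name="x",
                                    log_transform=False)
        settings = pdv.MBDSettings(generations=5_000, sample_every=20)
        r1 = pdv.run_mbd(reps, [s1], (0.0, 100.0), settings=settings, seed=3)
        r2 = pdv.run_mbd(reps, [s2], (0.0, 100.0), settings=settings, seed=3)
        pd.testing.assert_frame_equal(
            r1.shrinkage_summary(), r2.shrinkage_summary()
        )

    def test_reduction_to_bds_with_no_predictors(self, constant_rate_table):
        """With zero predictors the MBD posterior for (lambda0, mu0) must
        agree with a constant-rate BDS fit (overlapping 95% CIs in at
        least 9/10 seeds)."""
        reps = pdv.ReplicateSet([constant_rate_table])
        ages = np.round(np.arange(0, 30.05, 0.1), 9)
        X = np.empty((len(ages), 0))
        hits = 0
        for seed in range(10):
            mres = pdv.run_mbd(
                reps, (ages, X, []), (0.0, 30.0),
                settings=pdv.MBDSettings(generations=20_000, sample_every=20),
                seed=seed,
            )
            samples = mres.pooled_params()
            m_lo, m_hi = np.percentile(samples[:, 0], [2.5, 97.5])
            bres = pdv.BirthDeathShiftsModel(
                constant_rate_table, (0.0, 30.0)
            ).fit(generations=20_000, sample_every=20, seed=seed + 100)
            b_lo, b_hi = bres.rate_credible_interval("lambda")
            if max(m_lo, b_lo) < min(m_hi, b_hi):
                hits += 1
        assert hits >= 9

    def test_omega_monotone_in_effect_size(self):
        """Pooled shrinkage weight increases with the simulated effect
        size across {0, 0.25, 0.5, 1.0}."""
        raw = pdv.simulate_predictor_series(
            pdv.PredictorTruth(kind="ou", reversion=0.05), 60.0,
            seed=55, name="x",
        )
        s = pdv.standardize_series(raw.ages, raw.raw, 60.0, name="x",
                                   log_transform=False)
        settings = pdv.MBDSettings(generations=15_000, sample_every=30)
        mean_w = []
        for g in (0.0, 0.25, 0.5, 1.0):
            ws = []
            for seed in range(10):
                truth = SimulationTruth(
                    lambda0=0.06, mu0=0.04, g_lambda=(g,), g_mu=(0.0,),
                    t_start=60.0, n_founders=60, seed=1000 + seed,
                )
                tab = pdv.simulate_bd_lifespans(truth, [s])
                reps = pdv.ReplicateSet([tab])
                res = pdv.run_mbd(reps, [s], (0.0, 60.0),
                                  settings=settings, seed=seed)
                ss = res.shrinkage_summary()
                ws.append(float(
                    ss[(ss["rate"] == "lambda")]["mean_weight"].iloc[0]
                ))
            mean_w.append(np.mean(ws))
        assert mean_w == sorted(mean_w)

    def test_ess_exclusion_reported(self, mbd_dataset):
        reps, series = mbd_dataset
        settings = pdv.MBDSettings(
            generations=8_000, sample_every=20, ess_threshold=1e9
        )
        with pytest.raises(RuntimeError, match="ESS"):
            pdv.run_mbd(reps, series, (0.0, 100.0), settings=settings, seed=1)


class TestReconstructRates:
    def test_flat_curves_for_null_posterior(self, mbd_dataset):
        reps, series = mbd_dataset
        res = pdv.run_mbd(
            reps, series, (0.0, 100.0),
            settings=pdv.MBDSettings(generations=8_000, sample_every=20),
            seed=2,
        )
        # plug in a synthetic posterior concentrated at the truth
        p = res.model.n_predictors
        point = np.array([[0.2, 0.1] + [0.0] * (2 * p)])
        res.params = [np.repeat(point, 60, axis=0) for _ in res.params]
        curves = res.reconstruct_rates()
        lam = curves[curves["rate"] == "lambda"]
        np.testing.assert_allclose(lam["median"], 0.2, atol=1e-12)
        np.testing.assert_allclose(lam["lo"], lam["hi"])

    def test_median_matches_sort_oracle(self, mbd_dataset):
        reps, series = mbd_dataset
        res = pdv.run_mbd(
            reps, series, (0.0, 100.0),
            settings=pdv.MBDSettings(generations=8_000, sample_every=20),
            seed=2,
        )
        curves = res.reconstruct_rates()
        samples = res.pooled_params()
        p = res.model.n_predictors
        rng = np.random.default_rng(1)
        lam = curves[curves["rate"] == "lambda"].reset_index(drop=True)
        for i in rng.choice(len(lam), 3, replace=False):
            age = lam.loc[i, "age"]
            cell = min(int(age / 0.1), len(res.model.ages) - 1)
            x = res.model.X[cell]
            vals = samples[:, 0] * np.exp(samples[:, 2:2 + p] @ x)
            assert lam.loc[i, "median"] == pytest.approx(np.median(vals))
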