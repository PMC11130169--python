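"""Parameter determination: repair fit, likelihood, MCMC, inversion, R²."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from imkdose import (
    MCMCConfig,
    SigmaPolicy,
    derive_micro_params,
    fit_repair_rate,
    gen_foci,
    gen_survival_lognormal,
    log_likelihood,
    make_acute,
    mcmc_fit_survival,
    prediction_band,
    r_squared,
)
from imkdose.datasets import FOCI_COLUMNS
from imkdose.fitting import RepairFit


def _noise_free_foci(k_N, c, dose, times, schedule):
    """Exact model means written as a one-nucleus-per-timepoint table."""
    rows = []
    for t in times:
        mean = k_N * dose * np.exp(-c * (schedule.delivery_time + t))
        rows.append(("x", "acute", dose, t, "after_end", 0, mean))
        rows.append(("x", "acute", dose, t, "after_end", 1, mean))
    return pd.DataFrame(rows, columns=FOCI_COLUMNS)


class TestRepairFit:
    times = (0.5, 1.0, 2.5, 6.0, 24.0, 48.0)

    def test_noise_free_recovery_is_exact(self, acute_1gy):
        df = _noise_free_foci(40.6, 0.309, 1.0, self.times, acute_1gy)
        fit = fit_repair_rate(df, acute_1gy, 1.0)
        assert fit.k_N == pytest.approx(40.6, rel=1e-4)
        assert fit.c == pytest.approx(0.309, rel=1e-4)

    def test_poisson_data_recovery_within_2sd(self, hlec, acute_1gy):
        from imkdose.schedule import Timepoint

        tps = [Timepoint(t, "after_end") for t in self.times]
        df = gen_foci(hlec, acute_1gy, 1.0, tps, n_cells=100, lambda0=0.5, seed=11)
        bg = df[df["dose_Gy"] == 0]["foci_count"].mean()
        fit = fit_repair_rate(df, acute_1gy, 1.0, background=bg)
        assert abs(fit.c - 0.309) < 2 * fit.sd_c

    def test_too_few_timepoints_rejected(self, acute_1gy):
        df = _noise_free_foci(40.6, 0.309, 1.0, (0.5, 1.0), acute_1gy)
        with pytest.raises(ValueError, match="3 distinct"):
            fit_repair_rate(df, acute_1gy, 1.0)

    def test_all_zero_counts_rejected(self, acute_1gy):
        df = _noise_free_foci(40.6, 0.309, 1.0, self.times, acute_1gy)
        df["foci_count"] = 0
        with pytest.raises(ValueError):
            fit_repair_rate(df, acute_1gy, 1.0)


def _survival_frame(doses, sfs, se=None):
    return pd.DataFrame(
        {
            "cell_line": "x",
            "schedule_label": "acute",
            "dose_Gy": doses,
            "replicate": 0,
            "n_plated": np.nan,
            "colonies": np.nan,
            "sf": sfs,
            "se": se if se is not None else np.nan,
        }
    )


class TestLogLikelihood:
    def test_perfect_fit_leaves_only_normalization(self, hlec):
        theta = (hlec.alpha0, hlec.beta0, hlec.a_plus_c)
        doses = np.array([2.0, 4.0])
        T = doses / (1.82 * 60)
        from imkdose import lea_catcheside_F

        w = np.array(
            [
                (hlec.alpha0 + hlec.gamma * hlec.beta0) * d
                + lea_catcheside_F(hlec.a_plus_c, t) * hlec.beta0 * d**2
                for d, t in zip(doses, T)
            ]
        )
        df = _survival_frame(doses, np.exp(-w))
        sigma = 0.1
        ll = log_likelihood(theta, df, hlec.gamma, SigmaPolicy("fixed", sigma))
        assert ll == pytest.approx(2 * (-0.5 * np.log(2 * np.pi * sigma**2)), rel=1e-9)

    def test_independent_oracle_evaluation(self, hlec):
        # one-line re-derivation of the Gaussian likelihood on -ln S
        theta = (hlec.alpha0, hlec.beta0, hlec.a_plus_c)
        df = _survival_frame([2.0, 4.0], [0.30, 0.08])
        sigma = 0.1
        got = log_likelihood(theta, df, hlec.gamma, SigmaPolicy("fixed", sigma))
        from imkdose import lea_catcheside_F

        expected = 0.0
        for d, s_exp in [(2.0, 0.30), (4.0, 0.08)]:
            t = d / (1.82 * 60)
            w = (hlec.alpha0 + hlec.gamma * hlec.beta0) * d + lea_catcheside_F(
                hlec.a_plus_c, t
            ) * hlec.beta0 * d**2
            r = -np.log(s_exp) - w
            expected += -0.5 * np.log(2 * np.pi * sigma**2) - r**2 / (2 * sigma**2)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_residual_scaling_is_quadratic(self, hlec):
        theta = (hlec.alpha0, hlec.beta0, hlec.a_plus_c)
        base = _survival_frame([2.0, 4.0], [0.30, 0.08])
        ll0 = log_likelihood(theta, base, hlec.gamma, SigmaPolicy("fixed", 0.1))
        norm = 2 * (-0.5 * np.log(2 * np.pi * 0.1**2))
        # doubling every residual multiplies the quadratic penalty by 4
        from imkdose import lea_catcheside_F

        w_cal = np.array(
            [
                (hlec.alpha0 + hlec.gamma * hlec.beta0) * d
                + lea_catcheside_F(hlec.a_plus_c, d / (1.82 * 60)) * hlec.beta0 * d**2
                for d in (2.0, 4.0)
            ]
        )
        doubled_y = np.exp(-(w_cal + 2 * (-np.log([0.30, 0.08]) - w_cal)))
        ll2 = log_likelihood(theta, _survival_frame([2.0, 4.0], doubled_y), hlec.gamma, SigmaPolicy("fixed", 0.1))
        assert (ll2 - norm) == pytest.approx(4 * (ll0 - norm), rel=1e-9)

    def test_nonpositive_sf_rejected(self, hlec):
        df = _survival_frame([2.0], [0.0])
        with pytest.raises(ValueError):
            log_likelihood((0.5, 0.02, 0.3), df, hlec.gamma)


class TestMCMC:
    def test_same_seed_identical_chains(self, hlec):
        surv = gen_survival_lognormal(hlec, [2, 4, 6, 10], seed=1)
        cfg = MCMCConfig(burn_in=200, n_samples=500, seed=42)
        f1 = mcmc_fit_survival(surv, hlec.gamma, (0.309, 0.056), cfg)
        f2 = mcmc_fit_survival(surv, hlec.gamma, (0.309, 0.056), cfg)
        assert np.array_equal(f1.samples, f2.samples)
        assert f1.acceptance_rate == f2.acceptance_rate

    def test_noise_free_data_posterior_covers_truth(self, hlec_consistent):
        p = hlec_consistent
        surv = gen_survival_lognormal(p, [2, 4, 6, 10], cv=1e-9, replicates=1, seed=0)
        cfg = MCMCConfig(seed=3, sigma=SigmaPolicy("fixed", 0.02))
        fit = mcmc_fit_survival(surv, p.gamma, (0.309, 0.01), cfg)
        for name, truth in (("alpha0", p.alpha0), ("beta0", p.beta0)):
            assert abs(fit.mean(name) - truth) <= fit.sd(name)

    def test_synthetic_recovery_within_2sd(self, hlec_consistent):
        p = hlec_consistent
        surv = gen_survival_lognormal(p, [2, 4, 6, 10], cv=0.10, replicates=3, seed=4)
        fit = mcmc_fit_survival(surv, p.gamma, (0.309, 0.056), MCMCConfig(seed=5))
        assert abs(fit.mean("alpha0") - p.alpha0) <= 2 * fit.sd("alpha0")
        assert abs(fit.mean("beta0") - p.beta0) <= 2 * fit.sd("beta0")

    def test_too_few_doses_rejected(self, hlec):
        surv = _survival_frame([2.0, 4.0], [0.3, 0.08])
        with pytest.raises(ValueError, match="3 distinct"):
            mcmc_fit_survival(surv, hlec.gamma, (0.309, 0.056))

    def test_flat_likelihood_reproduces_uniform_prior(self, hlec):
        # detailed-balance smoke test: with an (effectively) flat
        # likelihood the stationary marginal of alpha0 is its uniform prior
        surv = _survival_frame([2.0, 4.0, 6.0], [0.5, 0.4, 0.3])
        cfg = MCMCConfig(seed=9, sigma=SigmaPolicy("fixed", 1e6))
        fit = mcmc_fit_survival(surv, hlec.gamma, (0.309, 0.056), cfg)
        thinned = fit.samples[::20, 0]  # decorrelate before the iid KS test
        stat, p = sps.kstest(thinned, "uniform", args=(0.0, 5.0))
        assert p > 0.01

    def test_sampled_sigma_mode_runs_and_reports(self, hlec_consistent):
        surv = gen_survival_lognormal(hlec_consistent, [2, 4, 6, 10], cv=0.1, seed=6)
        cfg = MCMCConfig(burn_in=500, n_samples=2000, seed=7, sigma=SigmaPolicy("sampled"))
        fit = mcmc_fit_survival(surv, hlec_consistent.gamma, (0.309, 0.056), cfg)
        assert "sigma" in fit.param_names
        assert fit.mean("sigma") > 0

    def test_posterior_serialization(self, hlec):
        surv = gen_survival_lognormal(hlec, [2, 4, 6, 10], seed=1)
        fit = mcmc_fit_survival(
            surv, hlec.gamma, (0.309, 0.056), MCMCConfig(burn_in=100, n_samples=200, seed=2)
        )
        import json

        blob = json.loads(fit.to_json())
        assert blob["n_samples"] == 200
        df = fit.samples_frame(thin=10)
        assert len(df) == 20
        assert "log_post" in df.columns


class TestDeriveMicroParams:
    def test_reference_summaries_reproduce_rates(self):
        # build a degenerate posterior at the reference summary point
        from imkdose.fitting import PosteriorFit

        samples = np.tile([0.559, 0.0175, 0.309], (100, 1))
        samples += np.random.default_rng(0).normal(0, 1e-12, samples.shape)
        fit = PosteriorFit(
            samples=samples,
            param_names=("alpha0", "beta0", "a_plus_c"),
            burn_in=0,
            n_samples=100,
            acceptance_rate=0.5,
            seed=0,
            log_post=np.zeros(100),
            config=MCMCConfig(),
        )
        repair = RepairFit(k_N=40.6, c=0.305, sd_k_N=0.0, sd_c=0.0, dose=1.0, residuals=np.zeros(1))
        a, b, _, _ = derive_micro_params(fit, repair)
        assert a == pytest.approx(4.27e-3, rel=0.03)
        assert b == pytest.approx(6.58e-6, rel=0.03)


class TestRSquared:
    def test_perfect_fit(self):
        assert r_squared([1, 2, 3], [1, 2, 3]) == 1.0

    def test_mean_model_scores_zero(self):
        assert r_squared([1, 2, 3], [2, 2, 2]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        assert r_squared([1, 2, 3], [1.1, 1.9, 3.2]) == pytest.approx(0.97, rel=1e-9)

    def test_affine_rescaling_of_both_series(self):
        obs, cal = np.array([1.0, 2, 3]), np.array([1.1, 1.9, 3.2])
        assert r_squared(5 * obs + 2, 5 * cal + 2) == pytest.approx(
            r_squared(obs, cal), rel=1e-12
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            r_squared([2, 2, 2], [1, 2, 3])


class TestPredictionBand:
    def _degenerate_fit(self, point):
        from imkdose.fitting import PosteriorFit

        samples = np.tile(point, (50, 1))
        return PosteriorFit(
            samples=samples,
            param_names=("alpha0", "beta0", "a_plus_c"),
            burn_in=0,
            n_samples=50,
            acceptance_rate=0.5,
            seed=0,
            log_post=np.zeros(50),
            config=MCMCConfig(),
        )

    def test_degenerate_posterior_zero_width(self):
        fit = self._degenerate_fit([0.5, 0.02, 0.3])
        band = prediction_band(fit, lambda th, q: th[0] * q, [1.0, 2.0])
        assert np.allclose(band[:, 0], band[:, 1])

    def test_survival_band_at_zero_dose_is_one(self, hlec):
        surv = gen_survival_lognormal(hlec, [2, 4, 6, 10], seed=1)
        fit = mcmc_fit_survival(
            surv, hlec.gamma, (0.309, 0.056), MCMCConfig(burn_in=200, n_samples=500, seed=2)
        )
        band = prediction_band(
            fit, lambda th, q: np.exp(-((th[0] + 0.954 * th[1]) * q + th[1] * q**2)), [0.0]
        )
        assert np.allclose(band, 1.0)

    def test_band_width_grows_with_posterior_scatter(self):
        rng = np.random.default_rng(0)
        base = self._degenerate_fit([0.5, 0.02, 0.3])
        narrow = base.samples + rng.normal(0, 0.01, base.samples.shape)
        wide = base.samples + rng.normal(0, 0.05, base.samples.shape)
        from dataclasses import replace

        b1 = prediction_band(replace(base, samples=narrow), lambda th, q: th[0], [0])
        b2 = prediction_band(replace(base, samples=wide), lambda th, q: th[0], [0])
        assert (b2[0, 1] - b2[0, 0]) > (b1[0, 1] - b1[0, 0])
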