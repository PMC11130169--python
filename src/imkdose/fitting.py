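"""Four-step parameter determination.

Given acute-exposure data, the cell-specific parameters are estimated in
the order the model structure dictates:

  (ii)  the DSB repair rate c and initial yield k_N from a nonlinear
        least-squares fit of k_N·e^{-ct} to mean focus counts vs time;
  (iii) the survival coefficients (α0, β0, a+c) by random-walk Metropolis
        MCMC on the clonogenic dose–response, with the step-(ii) c as
        prior information for a+c;
  (iv)  the microscopic rates (a, b) by algebraic inversion of the
        α0/β0 relations, with delta-method error propagation.

(Step (i), the microdosimetric γ, is a config input here — it comes from
track-structure simulation, outside this package's scope.)

The likelihood is Gaussian on -ln S.  Its width σ is not a measured
quantity; a σ policy chooses between the per-point experimental SE, a
fixed constant, or sampling σ as a nuisance parameter with a Jeffreys-like
1/σ prior.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .params import CellParams
from .schedule import DoseSchedule, Timepoint, absolute_time
from .survival import lea_catcheside_F, micro_from_alpha0_beta0

__all__ = [
    "RepairFit",
    "SigmaPolicy",
    "MCMCConfig",
    "PosteriorFit",
    "fit_repair_rate",
    "log_likelihood",
    "mcmc_fit_survival",
    "derive_micro_params",
    "r_squared",
    "prediction_band",
]


# ---------------------------------------------------------------------------
# step (ii): exponential repair fit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RepairFit:
    """Result of the exponential repair fit k_N·D·e^{-ct}."""

    k_N: float  # initial DSB yield per nucleus per Gy
    c: float  # repair rate, 1/h
    sd_k_N: float
    sd_c: float
    dose: float
    residuals: np.ndarray

    def __post_init__(self) -> None:
        if self.k_N <= 0 or self.c <= 0:
            raise ValueError("fitted k_N and c must be positive")


def fit_repair_rate(
    foci: pd.DataFrame,
    schedule: DoseSchedule,
    dose: float,
    background: float = 0.0,
) -> RepairFit:
    """Fit A·e^{-ct} to mean focus counts after one acute exposure.

    Times are placed on the absolute clock via the schedule; the fitted
    amplitude is scaled by the dose to give k_N per Gy.  ``background``
    (e.g. the 0 Gy control mean) is subtracted from the observed means
    before fitting.
    """
    irradiated = foci[foci["dose_Gy"] > 0]
    if irradiated.empty or (irradiated["foci_count"] <= 0).all():
        raise ValueError("no non-zero focus counts to fit")
    groups = irradiated.groupby(["timepoint_h", "reference"])["foci_count"].mean()
    times = np.array(
        [absolute_time(schedule, Timepoint(tp, ref)) for (tp, ref) in groups.index]
    )
    means = groups.to_numpy(dtype=float) - background
    if len(times) < 3:
        raise ValueError("need at least 3 distinct timepoints for the repair fit")
    order = np.argsort(times)
    times, means = times[order], means[order]

    def model(t, A, c):
        return A * np.exp(-c * t)

    p0 = (max(means.max(), 1e-3), 0.3)
    popt, pcov = optimize.curve_fit(model, times, means, p0=p0, maxfev=10000)
    A, c = popt
    if A <= 0 or c <= 0:
        raise ValueError(f"degenerate repair fit: A={A:g}, c={c:g}")
    sd_A, sd_c = np.sqrt(np.diag(pcov))
    return RepairFit(
        k_N=A / dose,
        c=c,
        sd_k_N=sd_A / dose,
        sd_c=sd_c,
        dose=dose,
        residuals=means - model(times, *popt),
    )


# ---------------------------------------------------------------------------
# step (iii): MCMC survival fit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SigmaPolicy:
    """Width of the Gaussian likelihood on -ln S.

    mode: "auto" (per-point SE when the table has one, else fixed),
    "se", "fixed", or "sampled" (σ a nuisance parameter, 1/σ prior).
    """

    mode: str = "auto"
    value: float = 0.1

    def __post_init__(self) -> None:
        if self.mode not in ("auto", "se", "fixed", "sampled"):
            raise ValueError(f"unknown sigma policy mode {self.mode!r}")
        if self.value <= 0:
            raise ValueError("sigma value must be positive")

    def resolve(self, survival: pd.DataFrame) -> str:
        if self.mode != "auto":
            return self.mode
        if "se" in survival.columns and survival["se"].notna().all() and (survival["se"] > 0).all():
            return "se"
        return "fixed"


@dataclass(frozen=True)
class MCMCConfig:
    burn_in: int = 1_000
    n_samples: int = 10_000
    seed: int = 20240528
    sigma: SigmaPolicy = field(default_factory=SigmaPolicy)
    alpha0_bounds: tuple[float, float] = (0.0, 5.0)  # Gy^-1, uniform prior
    beta0_bounds: tuple[float, float] = (0.0, 1.0)  # Gy^-2, uniform prior
    dose_rate_per_min: float = 1.82  # acute delivery rate for S_cal
    adapt_window: int = 100  # burn-in acceptance window for step tuning
    target_acceptance: tuple[float, float] = (0.20, 0.45)


def _neg_log_s_cal(
    alpha0: float, beta0: float, a_plus_c: float, gamma: float, D: np.ndarray, T: np.ndarray
) -> np.ndarray:
    x = a_plus_c * T
    F = np.where(x < 1e-4, 1.0 - x / 3.0 + x * x / 12.0, 2.0 / np.maximum(x * x, 1e-300) * (x + np.expm1(-x)))
    return (alpha0 + gamma * beta0) * D + F * beta0 * D * D


def log_likelihood(
    theta,
    survival: pd.DataFrame,
    gamma: float,
    sigma_policy: SigmaPolicy = SigmaPolicy(),
    dose_rate_per_min: float = 1.82,
) -> float:
    """Gaussian log likelihood of (α0, β0, a+c) on the -ln S scale.

    Each dose point is delivered acutely at ``dose_rate_per_min``, so the
    calculated survival carries its own (tiny) protraction factor.
    """
    alpha0, beta0, a_plus_c = theta[:3]
    survival = survival[survival["sf"].notna()]
    if (survival["sf"] <= 0).any():
        raise ValueError("measured surviving fractions must be positive")
    D = survival["dose_Gy"].to_numpy(dtype=float)
    T = D / (dose_rate_per_min * 60.0)  # hours
    y = -np.log(survival["sf"].to_numpy(dtype=float))
    mode = sigma_policy.resolve(survival)
    if mode == "se":
        # SE on S -> SE on -ln S by the delta method: se(lnS) = se(S)/S
        sigma = survival["se"].to_numpy(dtype=float) / survival["sf"].to_numpy(dtype=float)
    elif mode == "sampled":
        sigma = np.full_like(y, float(theta[3]))
    else:
        sigma = np.full_like(y, sigma_policy.value)
    w = _neg_log_s_cal(alpha0, beta0, a_plus_c, gamma, D, T)
    resid = y - w
    return float(np.sum(-0.5 * np.log(2 * np.pi * sigma**2) - resid**2 / (2 * sigma**2)))


@dataclass(frozen=True)
class PosteriorFit:
    """Metropolis chain output: retained samples plus summaries.

    ``samples`` has one column per parameter in ``param_names``
    ((alpha0, beta0, a_plus_c) and, under the sampled-σ policy, sigma).
    """

    samples: np.ndarray
    param_names: tuple[str, ...]
    burn_in: int
    n_samples: int
    acceptance_rate: float
    seed: int
    log_post: np.ndarray
    config: MCMCConfig

    def __post_init__(self) -> None:
        if self.samples.shape[0] != self.n_samples:
            raise ValueError("sample count does not match configuration")
        if not (0.0 < self.acceptance_rate < 1.0):
            raise ValueError("acceptance rate must lie strictly in (0, 1)")

    def summary(self) -> dict[str, tuple[float, float]]:
        return {
            name: (float(self.samples[:, i].mean()), float(self.samples[:, i].std(ddof=1)))
            for i, name in enumerate(self.param_names)
        }

    def mean(self, name: str) -> float:
        return float(self.samples[:, self.param_names.index(name)].mean())

    def sd(self, name: str) -> float:
        return float(self.samples[:, self.param_names.index(name)].std(ddof=1))

    def to_json(self) -> str:
        return json.dumps(
            {
                "param_names": list(self.param_names),
                "summaries": {k: {"mean": m, "sd": s} for k, (m, s) in self.summary().items()},
                "burn_in": self.burn_in,
                "n_samples": self.n_samples,
                "acceptance_rate": self.acceptance_rate,
                "seed": self.seed,
            }
        )

    def samples_frame(self, thin: int = 1) -> pd.DataFrame:
        df = pd.DataFrame(self.samples[::thin], columns=list(self.param_names))
        df["log_post"] = self.log_post[::thin]
        return df


def mcmc_fit_survival(
    survival: pd.DataFrame,
    gamma: float,
    prior_c: RepairFit | tuple[float, float],
    config: MCMCConfig = MCMCConfig(),
) -> PosteriorFit:
    """Random-walk Metropolis fit of (α0, β0, a+c) to a survival table.

    Priors: uniform on (α0, β0) inside ``config`` bounds; Gaussian on a+c
    centered at the repair-fit c with its fit SD, truncated to positives —
    the repair rate is prior information but the value is updated by the
    survival data.  Step sizes adapt toward a 20–45% acceptance window
    during burn-in only, then freeze (preserving ergodicity); the chain is
    fully deterministic under the config seed.
    """
    data = survival[(survival["dose_Gy"] > 0) & survival["sf"].notna()]
    if data["dose_Gy"].nunique() < 3:
        raise ValueError("need at least 3 distinct dose points")
    c_mean, c_sd = (
        (prior_c.c, max(prior_c.sd_c, 1e-6)) if isinstance(prior_c, RepairFit) else prior_c
    )
    if c_mean <= 0:
        raise ValueError("prior repair rate must be positive")

    sampled_sigma = config.sigma.resolve(data) == "sampled"
    names = ("alpha0", "beta0", "a_plus_c") + (("sigma",) if sampled_sigma else ())
    ndim = len(names)

    # precompute data vectors once; the likelihood is evaluated ~1e4 times
    D = data["dose_Gy"].to_numpy(dtype=float)
    T = D / (config.dose_rate_per_min * 60.0)
    y = -np.log(data["sf"].to_numpy(dtype=float))
    mode = config.sigma.resolve(data)
    fixed_sigma = None
    if mode == "se":
        fixed_sigma = data["se"].to_numpy(dtype=float) / data["sf"].to_numpy(dtype=float)
    elif mode == "fixed":
        fixed_sigma = np.full_like(y, config.sigma.value)

    lo = np.array([config.alpha0_bounds[0], config.beta0_bounds[0], 0.0] + ([1e-6] if sampled_sigma else []))
    hi = np.array(
        [config.alpha0_bounds[1], config.beta0_bounds[1], np.inf]
        + ([np.inf] if sampled_sigma else [])
    )

    def log_post(th: np.ndarray) -> float:
        if np.any(th <= lo) or np.any(th >= hi):
            return -np.inf
        alpha0, beta0, ac = th[:3]
        sigma = th[3] if sampled_sigma else fixed_sigma
        w = _neg_log_s_cal(alpha0, beta0, ac, gamma, D, T)
        resid = y - w
        ll = float(np.sum(-0.5 * np.log(2 * np.pi * sigma**2) - resid**2 / (2 * sigma**2)))
        lp = -0.5 * ((ac - c_mean) / c_sd) ** 2  # truncated-normal prior on a+c
        if sampled_sigma:
            lp += -math.log(th[3])  # Jeffreys-like 1/sigma
        return ll + lp

    rng = np.random.default_rng(config.seed)
    # start near a crude LQ estimate: w/D ≈ (α0 + γβ0) + β0·D for near-acute
    # delivery, so a degree-1 polynomial gives workable initial values
    c1, c0 = np.polyfit(D, y / D, 1)
    beta0_init = float(np.clip(c1, 1e-4, 0.9 * config.beta0_bounds[1]))
    alpha0_init = float(np.clip(c0 - gamma * beta0_init, 1e-3, 0.9 * config.alpha0_bounds[1]))
    theta = np.array(
        [alpha0_init, beta0_init, c_mean] + ([config.sigma.value] if sampled_sigma else [])
    )
    lp_cur = log_post(theta)
    step = np.array([0.05, 0.005, 0.5 * c_sd] + ([0.02] if sampled_sigma else []))

    # burn-in with windowed step adaptation
    window_acc = 0
    for i in range(config.burn_in):
        cand = theta + step * rng.standard_normal(ndim)
        lp_cand = log_post(cand)
        if math.log(rng.random()) < lp_cand - lp_cur:
            theta, lp_cur = cand, lp_cand
            window_acc += 1
        if (i + 1) % config.adapt_window == 0:
            rate = window_acc / config.adapt_window
            if rate == 0.0 and i + 1 == config.burn_in:
                raise RuntimeError("zero acceptance over a full adaptation window")
            if rate < config.target_acceptance[0]:
                step *= 0.7
            elif rate > config.target_acceptance[1]:
                step *= 1.3
            window_acc = 0

    samples = np.empty((config.n_samples, ndim))
    log_posts = np.empty(config.n_samples)
    accepted = 0
    for i in range(config.n_samples):
        cand = theta + step * rng.standard_normal(ndim)
        lp_cand = log_post(cand)
        if math.log(rng.random()) < lp_cand - lp_cur:
            theta, lp_cur = cand, lp_cand
            accepted += 1
        samples[i] = theta
        log_posts[i] = lp_cur

    return PosteriorFit(
        samples=samples,
        param_names=names,
        burn_in=config.burn_in,
        n_samples=config.n_samples,
        acceptance_rate=accepted / config.n_samples,
        seed=config.seed,
        log_post=log_posts,
        config=config,
    )


# ---------------------------------------------------------------------------
# step (iv): inversion to microscopic rates
# ---------------------------------------------------------------------------


def derive_micro_params(fit: PosteriorFit, repair: RepairFit) -> tuple[float, float, float, float]:
    """(a, b, sd_a, sd_b) from posterior summaries and the repair-fit k_N."""
    return micro_from_alpha0_beta0(
        k_N=repair.k_N,
        alpha0=fit.mean("alpha0"),
        beta0=fit.mean("beta0"),
        a_plus_c=fit.mean("a_plus_c"),
        sd_k_N=repair.sd_k_N,
        sd_alpha0=fit.sd("alpha0"),
        sd_beta0=fit.sd("beta0"),
        sd_a_plus_c=fit.sd("a_plus_c"),
    )


def r_squared(observed, calculated) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot; 1 iff the two series
    coincide, ≤ 1 always, undefined for zero-variance observations."""
    obs = np.asarray(observed, dtype=float)
    cal = np.asarray(calculated, dtype=float)
    if obs.shape != cal.shape or obs.size < 2:
        raise ValueError("need two equal-length series of at least 2 points")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed series has zero variance")
    return 1.0 - float(np.sum((obs - cal) ** 2)) / ss_tot


def prediction_band(
    fit: PosteriorFit,
    model_fn,
    queries,
    level: float = 0.683,
    thin: int = 1,
) -> np.ndarray:
    """Central posterior-predictive interval of ``model_fn(theta, query)``.

    Returns an array of shape (len(queries), 2) with the lower/upper
    percentiles of the model output over the (thinned) posterior samples;
    for a 1σ-equivalent band use the default level 0.683.
    """
    samples = fit.samples[::thin]
    if samples.size == 0:
        raise ValueError("empty posterior")
    q_lo, q_hi = 50 * (1 - level), 50 * (1 + level)
    out = np.empty((len(queries), 2))
    for j, q in enumerate(queries):
        vals = np.array([model_fn(th, q) for th in samples])
        out[j] = np.percentile(vals, [q_lo, q_hi])
    return out
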