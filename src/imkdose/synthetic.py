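"""Synthetic assay data with the statistical structure the analysis assumes.

Stands in for the two wet-lab assays:

* γ-H2AX focus formation — per-nucleus counts drawn Poisson around the
  model mean λ0 + δ_N(t) (background plus expected lesions), ~100 nuclei
  per timepoint; an optional negative-binomial knob adds the
  overdispersion real focus distributions often show.
* clonogenic survival — colonies drawn Binomial(n_plated, pe0·S_model)
  with the dose-tiered plating design (10³ at 0 Gy, 3·10³ at 2 and 4 Gy,
  5·10³ at 6 Gy, 10⁴ at 10 Gy); the surviving fraction is computed exactly
  as the assay defines it, as the ratio of plating efficiencies of the
  irradiated and the simulated unirradiated group.

Everything is deterministic under the seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datasets import FOCI_COLUMNS, SURVIVAL_COLUMNS
from .kinetics import foci_expected
from .params import CellParams
from .schedule import (
    DoseSchedule,
    FractionSpec,
    Timepoint,
    absolute_time,
    make_acute,
    make_continuous,
    make_fractionated,
)
from .survival import neg_log_survival, surviving_fraction

__all__ = [
    "gen_foci",
    "gen_survival",
    "gen_survival_lognormal",
    "reference_scenarios",
    "PLATING_DESIGN",
    "DEFAULT_TIMEPOINTS",
]

#: cells plated per flask at each dose (Gy) in the clonogenic design
PLATING_DESIGN = {0.0: 1_000, 2.0: 3_000, 4.0: 3_000, 6.0: 5_000, 10.0: 10_000}

#: early observations anchored after the end of delivery, late after the start
DEFAULT_TIMEPOINTS = (
    Timepoint(0.5, "after_end"),
    Timepoint(1.0, "after_end"),
    Timepoint(24.0, "after_start"),
    Timepoint(48.0, "after_start"),
)


def gen_foci(
    params: CellParams,
    s: DoseSchedule,
    dose: float,
    timepoints=DEFAULT_TIMEPOINTS,
    n_cells: int = 100,
    lambda0: float = 0.5,
    seed: int = 0,
    cell_line: str = "synthetic",
    overdispersion: float = 0.0,
    include_control: bool = True,
) -> pd.DataFrame:
    """Per-nucleus focus counts for one regimen.

    Counts are Poisson(λ0 + δ_N(t)); with ``overdispersion`` φ > 0 they
    are negative-binomial with variance μ(1+φμ) instead.  The 0 Gy control
    (pure background) is included by default.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if lambda0 < 0:
        raise ValueError("background rate must be non-negative")
    if abs(dose - s.total_dose) > 1e-9 * max(1.0, dose):
        raise ValueError("dose must equal the schedule's total dose")
    rng = np.random.default_rng(seed)
    rows = []

    def draw(mu: float, n: int) -> np.ndarray:
        if mu == 0.0:
            return np.zeros(n, dtype=int)
        if overdispersion > 0:
            r = 1.0 / overdispersion
            p = r / (r + mu)
            return rng.negative_binomial(r, p, size=n)
        return rng.poisson(mu, size=n)

    for tp in timepoints:
        t_abs = absolute_time(s, tp)
        mu = lambda0 + foci_expected(t_abs, s, params)
        for dose_val, mu_val in ((dose, mu),) + (((0.0, lambda0),) if include_control else ()):
            counts = draw(mu_val, n_cells)
            for i, cnt in enumerate(counts):
                rows.append(
                    (
                        cell_line,
                        s.label,
                        dose_val,
                        tp.offset,
                        tp.reference,
                        i,
                        int(cnt),
                    )
                )
    df = pd.DataFrame(rows, columns=FOCI_COLUMNS)
    df.attrs.update({"seed": seed, "lambda0": lambda0, "n_cells": n_cells})
    return df


def gen_survival(
    params: CellParams,
    doses,
    schedules=None,
    pe0: float = 0.3,
    replicates: int = 3,
    seed: int = 0,
    cell_line: str = "synthetic",
    dose_rate_per_min: float = 1.82,
    plating: dict | None = None,
) -> pd.DataFrame:
    """Clonogenic-assay emulator.

    One schedule per positive dose (acute at ``dose_rate_per_min`` unless
    ``schedules`` supplies them).  Each replicate simulates its own 0 Gy
    control; surviving fractions are ratios of plating efficiencies, so
    pe0 cancels in expectation.
    """
    if not 0 < pe0 <= 1:
        raise ValueError("plating efficiency must lie in (0, 1]")
    plating = dict(PLATING_DESIGN if plating is None else plating)
    doses = [float(d) for d in doses]
    for d in doses:
        if d > 0 and d not in plating:
            raise ValueError(f"no plating rule for dose {d} Gy; pass an override")
    if schedules is None:
        schedules = {d: make_acute(d, dose_rate_per_min) for d in doses if d > 0}
    else:
        schedules = {d: s for d, s in zip(doses, schedules) if d > 0}
    rng = np.random.default_rng(seed)
    rows = []
    n0 = plating.get(0.0, 1_000)
    for rep in range(replicates):
        ctrl_colonies = rng.binomial(n0, pe0)
        pe_ctrl = max(ctrl_colonies, 1) / n0
        rows.append((cell_line, "control", 0.0, rep, n0, int(ctrl_colonies), 1.0, 0.0))
        for d in doses:
            if d <= 0:
                continue
            sched = schedules[d]
            S = surviving_fraction(d, sched, params)
            n = plating[d]
            colonies = rng.binomial(n, pe0 * S)
            if colonies == 0:
                # no colonies -> surviving fraction unmeasurable in this flask
                sf = se = np.nan
            else:
                p_hat = colonies / n
                sf = p_hat / pe_ctrl
                se = np.sqrt(p_hat * (1 - p_hat) / n) / pe_ctrl
            rows.append((cell_line, sched.label, d, rep, n, int(colonies), sf, se))
    df = pd.DataFrame(rows, columns=SURVIVAL_COLUMNS)
    df.attrs.update({"seed": seed, "pe0": pe0})
    return df


def gen_survival_lognormal(
    params: CellParams,
    doses,
    cv: float = 0.10,
    replicates: int = 3,
    seed: int = 0,
    cell_line: str = "synthetic",
    dose_rate_per_min: float = 1.82,
) -> pd.DataFrame:
    """Surviving fractions with multiplicative lognormal noise of the given
    coefficient of variation — the idealized-noise counterpart of the
    binomial assay emulator, convenient for parameter-recovery studies."""
    rng = np.random.default_rng(seed)
    sig = np.sqrt(np.log1p(cv**2))
    rows = []
    for rep in range(replicates):
        for d in doses:
            if d <= 0:
                continue
            sched = make_acute(d, dose_rate_per_min)
            S = surviving_fraction(d, sched, params)
            sf = S * rng.lognormal(-0.5 * sig**2, sig)  # mean-one noise
            rows.append((cell_line, sched.label, float(d), rep, np.nan, np.nan, sf, np.nan))
    df = pd.DataFrame(rows, columns=SURVIVAL_COLUMNS)
    df.attrs.update({"seed": seed, "cv": cv})
    return df


def reference_scenarios(total_dose: float = 1.0) -> list[tuple[DoseSchedule, tuple[Timepoint, ...]]]:
    """The five dose-rate regimens of the study design, each paired with
    the standard observation timepoints.

    Acute 1.82 Gy/min X-rays; 0.2 Gy fractions every 120 s (0.1 Gy/min
    average); 0.05 Gy fractions every 90 s (0.033 Gy/min average);
    continuous γ-rays at 0.00461 and 0.00081 Gy/min.  The default total
    dose of 1 Gy makes the lowest-rate delivery last ~20.6 h, leaving the
    noted ~3.4 h gap before the 24 h observation.
    """
    if total_dose <= 0:
        raise ValueError("total_dose must be positive")

    def train(dose_per_fr: float, interval_s: float) -> DoseSchedule:
        n = round(total_dose / dose_per_fr)
        if abs(n * dose_per_fr - total_dose) > 1e-9:
            raise ValueError(
                f"total dose {total_dose} Gy is not a whole number of {dose_per_fr} Gy fractions"
            )
        return make_fractionated(FractionSpec(dose_per_fr, n, interval_s, 1.82))

    schedules = [
        make_acute(total_dose, 1.82),
        train(0.2, 120.0),
        train(0.05, 90.0),
        make_continuous(total_dose, 0.00461),
        make_continuous(total_dose, 0.00081),
    ]
    return [(s, DEFAULT_TIMEPOINTS) for s in schedules]
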