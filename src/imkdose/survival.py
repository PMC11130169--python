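"""Closed-form clonogenic survival under protracted exposure.

Assuming Poisson statistics for lethal lesions, -ln S equals the expected
LL plateau, which for a constant-rate exposure of dose D over time T is

    -ln S = (α0 + γβ0)·D + F·β0·D²,
    F = 2/((a+c)²T²) · [(a+c)T + e^{-(a+c)T} - 1],

the Lea–Catcheside dose-protraction factor.  F → 1 for an acute pulse and
→ 0 as delivery is stretched; it multiplies only the inter-track quadratic
term — same-event (intra-track) PLL pairs are co-temporal and cannot be
spared by protraction, which is why γβ0·D stays unprotracted.

The LQ coefficients are tied to the microscopic rates by
α0 = a·k_N/(a+c) and β0 = b·k_N²/(2(a+c)); both directions of that map are
provided, the inverse with first-order (delta-method) error propagation.
"""

from __future__ import annotations

import math

import numpy as np

from .params import CellParams
from .schedule import DoseSchedule

__all__ = [
    "lea_catcheside_F",
    "neg_log_survival",
    "neg_log_survival_acute",
    "surviving_fraction",
    "alpha0_beta0_from_micro",
    "micro_from_alpha0_beta0",
]


def lea_catcheside_F(a_plus_c: float, T: float) -> float:
    """Dose-protraction factor F ∈ (0, 1]; F(0) = 1 exactly.

    Uses the series expansion 1 - x/3 + x²/12 - ... for small x = (a+c)·T
    where the direct expression loses precision.
    """
    if a_plus_c <= 0:
        raise ValueError("a_plus_c must be positive")
    if T < 0:
        raise ValueError("T must be non-negative")
    x = a_plus_c * T
    if x < 1e-4:
        # F = 2(x + e^{-x} - 1)/x² expanded around 0
        return 1.0 - x / 3.0 + x * x / 12.0
    return 2.0 / (x * x) * (x + math.expm1(-x))


def neg_log_survival(D: float, s: DoseSchedule, p: CellParams, dose_tol: float = 1e-9) -> float:
    """-ln S for dose D delivered by schedule s.

    D must match the schedule's total dose (the schedule *is* the delivery
    of D); the protraction factor uses the schedule's delivery time.
    """
    if abs(D - s.total_dose) > dose_tol * max(1.0, D):
        raise ValueError(
            f"dose {D:g} Gy does not match schedule total dose {s.total_dose:g} Gy"
        )
    F = lea_catcheside_F(p.a_plus_c, s.delivery_time)
    return (p.alpha0_eff + p.gamma * p.beta0_eff) * D + F * p.beta0_eff * D * D


def neg_log_survival_acute(D: float, p: CellParams) -> float:
    """Acute (T→0) limit: the plain LQ form (α0+γβ0)·D + β0·D² with F = 1."""
    if D < 0:
        raise ValueError("dose must be non-negative")
    return (p.alpha0_eff + p.gamma * p.beta0_eff) * D + p.beta0_eff * D * D


def surviving_fraction(D: float, s: DoseSchedule, p: CellParams) -> float:
    return math.exp(-neg_log_survival(D, s, p))


def alpha0_beta0_from_micro(p: CellParams) -> tuple[float, float]:
    """(α0, β0) from the microscopic rates: exact algebra, no a+c≈c
    shortcut."""
    if p.a is None or p.b is None:
        raise ValueError("microscopic rates a and b are required")
    alpha0 = p.a * p.k_N / p.a_plus_c
    beta0 = p.b * p.k_N**2 / (2 * p.a_plus_c)
    return alpha0, beta0


def micro_from_alpha0_beta0(
    k_N: float,
    alpha0: float,
    beta0: float,
    a_plus_c: float,
    sd_k_N: float = 0.0,
    sd_alpha0: float = 0.0,
    sd_beta0: float = 0.0,
    sd_a_plus_c: float = 0.0,
) -> tuple[float, float, float, float]:
    """Invert the LQ relations: a = α0(a+c)/k_N, b = 2β0(a+c)/k_N².

    Returns (a, b, sd_a, sd_b).  Uncertainties are first-order propagated
    assuming independent inputs:
        (sd_a/a)² = (sd_α0/α0)² + (sd_ac/ac)² + (sd_kN/kN)²
        (sd_b/b)² = (sd_β0/β0)² + (sd_ac/ac)² + (2·sd_kN/kN)²
    """
    for name, v in (("k_N", k_N), ("alpha0", alpha0), ("beta0", beta0), ("a_plus_c", a_plus_c)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    a = alpha0 * a_plus_c / k_N
    b = 2.0 * beta0 * a_plus_c / k_N**2
    rel_k = sd_k_N / k_N
    rel_ac = sd_a_plus_c / a_plus_c
    sd_a = a * math.sqrt((sd_alpha0 / alpha0) ** 2 + rel_ac**2 + rel_k**2)
    sd_b = b * math.sqrt((sd_beta0 / beta0) ** 2 + rel_ac**2 + (2 * rel_k) ** 2)
    return a, b, sd_a, sd_b
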