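"""Cell-specific model parameters and microdosimetric inputs.

The kinetic description uses the microscopic rate set (k_N, a, b, a+c, γ):
k_N is the initial DSB yield per nucleus per Gy, a the first-order rate at
which a potentially lethal lesion (PLL) converts to a lethal lesion (LL),
b the nucleus-level second-order PLL-pair interaction rate, c the repair
rate, and γ the dose-mean specific energy per event.  The survival
description uses the linear-quadratic coefficients (α0, β0, γ, a+c), which
are algebraically tied to the microscopic set by

    α0 = a·k_N/(a+c),     β0 = b·k_N²/(2(a+c)).

``CellParams`` can hold either side (or both) and derives the other.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources

__all__ = [
    "CellParams",
    "MicrodosimetrySpec",
    "gamma_from_microdosimetry",
    "load_reference_params",
    "KEV_PER_UM_TO_GY",
]

#: 1 keV deposited in 1 μm³ of unit-density matter, expressed in Gy.
KEV_PER_UM_TO_GY = 0.1602176634


@dataclass(frozen=True)
class MicrodosimetrySpec:
    """Beam/geometry inputs for the single-event dose factor γ.

    y_D : dose-mean lineal energy, keV/μm
    rho : domain density, g/cm³ (water-equivalent by default)
    r_d : domain radius, μm
    """

    y_D: float
    rho: float = 1.0
    r_d: float = 0.5

    def __post_init__(self) -> None:
        if self.y_D <= 0 or self.rho <= 0 or self.r_d <= 0:
            raise ValueError("all microdosimetry fields must be positive")


def gamma_from_microdosimetry(m: MicrodosimetrySpec) -> float:
    """γ = y_D / (ρ π r_d²), converted to Gy.

    The mean chord of a sphere of radius r_d gives the event-mean specific
    energy per unit track length; with y_D in keV/μm, ρ in g/cm³ and r_d in
    μm the conversion constant is 0.16022 Gy per keV/(g/cm³·μm³).
    """
    return m.y_D / (m.rho * math.pi * m.r_d**2) * KEV_PER_UM_TO_GY


@dataclass(frozen=True)
class CellParams:
    """Per-cell-line parameter set, with optional 1-sd uncertainties.

    Units: k_N Gy⁻¹; a, b, a_plus_c h⁻¹; alpha0 Gy⁻¹; beta0 Gy⁻²; gamma Gy.
    Missing side (microscopic or LQ) is derived from the other at access
    time via the α0/β0 relations.
    """

    k_N: float
    a_plus_c: float
    gamma: float
    a: float | None = None
    b: float | None = None
    alpha0: float | None = None
    beta0: float | None = None
    sd: dict = field(default_factory=dict)
    label: str = ""

    _CONSISTENCY_TOL = 0.05  # printed values are rounded to 3 sig figs

    def __post_init__(self) -> None:
        for name in ("k_N", "a_plus_c", "gamma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("a", "b", "alpha0", "beta0"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be strictly positive when given")
        if self.a is None and self.alpha0 is None:
            raise ValueError("need either a or alpha0")
        if self.b is None and self.beta0 is None:
            raise ValueError("need either b or beta0")
        if self.a is not None and self.a >= self.a_plus_c:
            raise ValueError("a must be smaller than a+c")
        # warn (not fail) if both sides are supplied but disagree beyond rounding
        if self.a is not None and self.alpha0 is not None:
            implied = self.a * self.k_N / self.a_plus_c
            if abs(self.alpha0 - implied) / self.alpha0 > self._CONSISTENCY_TOL:
                warnings.warn(
                    f"alpha0={self.alpha0:g} vs a*k_N/(a+c)={implied:g}: "
                    "inconsistent beyond 5%",
                    stacklevel=2,
                )
        if self.b is not None and self.beta0 is not None:
            implied = self.b * self.k_N**2 / (2 * self.a_plus_c)
            if abs(self.beta0 - implied) / self.beta0 > self._CONSISTENCY_TOL:
                warnings.warn(
                    f"beta0={self.beta0:g} vs b*k_N^2/(2(a+c))={implied:g}: "
                    "inconsistent beyond 5%",
                    stacklevel=2,
                )

    # -- derived accessors ----------------------------------------------
    @property
    def a_eff(self) -> float:
        """First-order PLL→LL rate, derived from α0 if not stored."""
        if self.a is not None:
            return self.a
        return self.alpha0 * self.a_plus_c / self.k_N

    @property
    def b_eff(self) -> float:
        """Second-order PLL-pair rate, derived from β0 if not stored."""
        if self.b is not None:
            return self.b
        return 2 * self.beta0 * self.a_plus_c / self.k_N**2

    @property
    def alpha0_eff(self) -> float:
        if self.alpha0 is not None:
            return self.alpha0
        return self.a * self.k_N / self.a_plus_c

    @property
    def beta0_eff(self) -> float:
        if self.beta0 is not None:
            return self.beta0
        return self.b * self.k_N**2 / (2 * self.a_plus_c)

    def with_consistent_lq(self) -> "CellParams":
        """Copy whose (α0, β0) are recomputed from the microscopic side, so
        that kinetic and survival formulas agree to machine precision."""
        return replace(
            self,
            alpha0=self.a_eff * self.k_N / self.a_plus_c,
            beta0=self.b_eff * self.k_N**2 / (2 * self.a_plus_c),
            a=self.a_eff,
            b=self.b_eff,
        )

    def with_consistent_micro(self) -> "CellParams":
        """Copy whose (a, b) are recomputed from the LQ side."""
        return replace(
            self,
            a=self.alpha0_eff * self.a_plus_c / self.k_N,
            b=2 * self.beta0_eff * self.a_plus_c / self.k_N**2,
            alpha0=self.alpha0_eff,
            beta0=self.beta0_eff,
        )

    # -- serialization ---------------------------------------------------
    _KEYMAP = {
        "k_N": "k_N_per_Gy",
        "a": "a_per_h",
        "b": "b_per_h",
        "a_plus_c": "a_plus_c_per_h",
        "alpha0": "alpha0_per_Gy",
        "beta0": "beta0_per_Gy2",
        "gamma": "gamma_Gy",
    }

    def to_dict(self) -> dict:
        out: dict = {"label": self.label}
        for attr, key in self._KEYMAP.items():
            v = getattr(self, attr)
            if v is not None:
                out[key] = v
        if self.sd:
            out["sd"] = {self._KEYMAP[k]: v for k, v in self.sd.items()}
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "CellParams":
        inv = {v: k for k, v in cls._KEYMAP.items()}
        kwargs: dict = {"label": d.get("label", "")}
        for key, attr in inv.items():
            if key in d:
                kwargs[attr] = d[key]
        if "sd" in d:
            kwargs["sd"] = {inv[k]: v for k, v in d["sd"].items()}
        return cls(**kwargs)


def load_reference_params() -> dict[str, CellParams]:
    """Packaged reference parameter sets for WI-38 fibroblasts and human
    lens epithelial cells (HLEC), fitted to acute 150 kVp X-ray data."""
    text = (
        resources.files("imkdose").joinpath("data/reference_cell_params.json").read_text()
    )
    raw = json.loads(text)
    return {k: CellParams.from_dict(v) for k, v in raw.items()}
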