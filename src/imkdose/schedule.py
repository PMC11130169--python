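"""Piecewise-constant dose-rate histories (irradiation schedules).

Every exposure regimen — a single acute pulse, a train of small fractions,
or a long continuous exposure — is represented as an ordered list of
non-overlapping constant-rate segments on an absolute clock that starts at
the beginning of irradiation.  Internal units are hours and Gy/hour
throughout; the convenience constructors accept the Gy/min rates in which
X-ray and gamma-ray irradiators are usually calibrated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

__all__ = [
    "ExposureSegment",
    "DoseSchedule",
    "FractionSpec",
    "Timepoint",
    "make_acute",
    "make_fractionated",
    "make_continuous",
    "average_dose_rate",
    "absolute_time",
    "equivalent_continuous",
]

#: minutes -> hours conversion for dose rates (Gy/min -> Gy/h)
MIN_TO_H = 60.0


@dataclass(frozen=True)
class ExposureSegment:
    """One constant-rate stretch of irradiation.

    Attributes
    ----------
    t_start, t_end : float
        Segment boundaries in hours since the start of irradiation.
    dose_rate : float
        Dose rate in Gy/hour (constant over the segment).
    """

    t_start: float
    t_end: float
    dose_rate: float

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError(
                f"segment must have t_end > t_start, got [{self.t_start}, {self.t_end}]"
            )
        if self.dose_rate < 0:
            raise ValueError(f"dose_rate must be >= 0, got {self.dose_rate}")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def dose(self) -> float:
        """Dose delivered by this segment, Gy."""
        return self.dose_rate * self.duration


@dataclass(frozen=True)
class DoseSchedule:
    """An ordered, non-overlapping list of exposure segments.

    ``nominal_span_h``, when set (fraction trains), is the nominal cycle
    length ``n_fractions * interval`` used for the quoted average dose
    rate; the physical delivery time is ``delivery_time``.
    """

    segments: tuple[ExposureSegment, ...]
    label: str = ""
    nominal_span_h: float | None = None

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("a schedule needs at least one segment")
        segs = tuple(self.segments)
        object.__setattr__(self, "segments", segs)
        for prev, cur in zip(segs, segs[1:]):
            if cur.t_start < prev.t_end:
                raise ValueError("segments must be time-ordered and non-overlapping")
        if self.total_dose <= 0:
            raise ValueError("schedule delivers zero dose")

    @property
    def total_dose(self) -> float:
        return sum(s.dose for s in self.segments)

    @property
    def t_start(self) -> float:
        return self.segments[0].t_start

    @property
    def t_end(self) -> float:
        return self.segments[-1].t_end

    @property
    def delivery_time(self) -> float:
        """Physical delivery time T in hours (first start to last end)."""
        return self.t_end - self.t_start

    @property
    def average_dose_rate_per_h(self) -> float:
        span = self.nominal_span_h if self.nominal_span_h is not None else self.delivery_time
        return self.total_dose / span

    def dose_rate_at(self, t: float) -> float:
        """Instantaneous dose rate (Gy/h) at time t (hours)."""
        for s in self.segments:
            if s.t_start <= t < s.t_end:
                return s.dose_rate
        return 0.0

    def dose_delivered_by(self, t: float) -> float:
        """Cumulative dose (Gy) delivered up to time t (hours)."""
        d = 0.0
        for s in self.segments:
            if t <= s.t_start:
                break
            d += s.dose_rate * (min(t, s.t_end) - s.t_start)
        return d

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "segments": [
                {
                    "t_start_h": s.t_start,
                    "t_end_h": s.t_end,
                    "dose_rate_Gy_per_h": s.dose_rate,
                }
                for s in self.segments
            ],
            **(
                {"nominal_span_h": self.nominal_span_h}
                if self.nominal_span_h is not None
                else {}
            ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DoseSchedule":
        if "type" in d:  # convenience constructor mirroring the regimen families
            kind = d["type"]
            if kind == "acute":
                return make_acute(d["dose_Gy"], d["dose_rate_Gy_per_min"], d.get("label", ""))
            if kind == "continuous":
                return make_continuous(d["dose_Gy"], d["dose_rate_Gy_per_min"], d.get("label", ""))
            if kind == "fractionated":
                spec = FractionSpec(
                    dose_per_fraction=d["dose_per_fraction_Gy"],
                    n_fractions=d["n_fractions"],
                    interval_s=d["interval_s"],
                    instantaneous_rate=d["instantaneous_rate_Gy_per_min"],
                )
                return make_fractionated(spec, d.get("label", ""))
            raise ValueError(f"unknown schedule type {kind!r}")
        segs = tuple(
            ExposureSegment(s["t_start_h"], s["t_end_h"], s["dose_rate_Gy_per_h"])
            for s in d["segments"]
        )
        return cls(segs, d.get("label", ""), d.get("nominal_span_h"))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "DoseSchedule":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class FractionSpec:
    """A fraction-train prescription: dose per fraction delivered at a high
    instantaneous rate, repeated at a fixed start-to-start interval."""

    dose_per_fraction: float  # Gy
    n_fractions: int
    interval_s: float  # seconds, start-to-start
    instantaneous_rate: float  # Gy/min during delivery

    def __post_init__(self) -> None:
        if self.dose_per_fraction <= 0 or self.n_fractions <= 0:
            raise ValueError("dose_per_fraction and n_fractions must be positive")
        if self.interval_s <= 0 or self.instantaneous_rate <= 0:
            raise ValueError("interval and instantaneous_rate must be positive")
        if self.delivery_time_s > self.interval_s:
            raise ValueError(
                f"per-fraction delivery time {self.delivery_time_s:.3g} s exceeds "
                f"the {self.interval_s:.3g} s interval"
            )

    @property
    def delivery_time_s(self) -> float:
        """Beam-on time per fraction, seconds."""
        return self.dose_per_fraction / self.instantaneous_rate * 60.0


@dataclass(frozen=True)
class Timepoint:
    """An observation time, anchored either to the start or the end of
    irradiation (early fixes are quoted after the end, late ones after the
    start)."""

    offset: float  # hours
    reference: str = "after_start"  # or "after_end"

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError("timepoint offset must be >= 0")
        if self.reference not in ("after_start", "after_end"):
            raise ValueError(f"unknown reference {self.reference!r}")


def make_acute(dose: float, dose_rate_per_min: float, label: str = "") -> DoseSchedule:
    """Single uninterrupted exposure of `dose` Gy at `dose_rate_per_min` Gy/min."""
    if dose <= 0 or dose_rate_per_min <= 0:
        raise ValueError("dose and dose_rate must be positive")
    rate_h = dose_rate_per_min * MIN_TO_H
    T = dose / rate_h
    return DoseSchedule(
        (ExposureSegment(0.0, T, rate_h),),
        label or f"acute {dose:g} Gy @ {dose_rate_per_min:g} Gy/min",
    )


def make_continuous(dose: float, dose_rate_per_min: float, label: str = "") -> DoseSchedule:
    """Continuous low-dose-rate exposure; same geometry as an acute pulse,
    just delivered over hours rather than seconds."""
    s = make_acute(dose, dose_rate_per_min)
    return DoseSchedule(
        s.segments, label or f"continuous {dose:g} Gy @ {dose_rate_per_min:g} Gy/min"
    )


def make_fractionated(spec: FractionSpec, label: str = "") -> DoseSchedule:
    """Fraction train: fraction i starts at ``i * interval`` (start-to-start
    convention; this is what makes 0.2 Gy per 120 s read as 0.1 Gy/min on
    average)."""
    rate_h = spec.instantaneous_rate * MIN_TO_H
    dur_h = spec.delivery_time_s / 3600.0
    interval_h = spec.interval_s / 3600.0
    segs = tuple(
        ExposureSegment(i * interval_h, i * interval_h + dur_h, rate_h)
        for i in range(spec.n_fractions)
    )
    return DoseSchedule(
        segs,
        label
        or f"{spec.dose_per_fraction:g} Gy/Fr x {spec.n_fractions} @ {spec.interval_s:g} s",
        nominal_span_h=spec.n_fractions * interval_h,
    )


def average_dose_rate(s: DoseSchedule, span: str = "nominal") -> float:
    """Average dose rate in Gy/min.

    span="nominal" uses the fraction-train cycle length (n x interval) when
    the schedule carries one — this reproduces the quoted 0.1 and
    0.033 Gy/min averages; span="actual" uses first-start-to-last-end.
    """
    if span == "nominal":
        rate_h = s.average_dose_rate_per_h
    elif span == "actual":
        rate_h = s.total_dose / s.delivery_time
    else:
        raise ValueError("span must be 'nominal' or 'actual'")
    return rate_h / MIN_TO_H


def absolute_time(s: DoseSchedule, tp: Timepoint) -> float:
    """Place a timepoint on the absolute clock (hours since irradiation
    start): after_start -> offset, after_end -> delivery time + offset."""
    if tp.reference == "after_start":
        return tp.offset
    return s.delivery_time + tp.offset


def equivalent_continuous(s: DoseSchedule) -> DoseSchedule:
    """Constant-rate surrogate: one segment with the same total dose over
    the schedule's (nominal, if set) span."""
    span = s.nominal_span_h if s.nominal_span_h is not None else s.delivery_time
    rate = s.total_dose / span
    return DoseSchedule(
        (ExposureSegment(s.t_start, s.t_start + span, rate),),
        label=f"{s.label} (equivalent continuous)" if s.label else "equivalent continuous",
    )
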