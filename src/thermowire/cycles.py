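"""Developmental outcomes under periodic temperature programs.

Two routes to the same predictions:

* closed forms for a symmetric two-level (step) cycle with mean T̄ and half
  amplitude ΔT:

      t̃/t̄ = 1 / cosh(alpha ΔT)
      ñ/n̄ = [cosh(gamma ΔT) / cosh(alpha ΔT)]^4,   gamma = alpha − beta/4

* a general integrator for arbitrary periodic waveforms (e.g. the 8-h hold /
  4-h ramp diurnal protocol), which reduces each quantity to period averages
  of the relative rate exp[s (T(τ) − T̄)]:

      t̃/t̄ = 1 / <e^{alpha ΔT(τ)}>,     ñ/n̄ = (<e^{gamma ΔT(τ)}> / <e^{alpha ΔT(τ)}>)^4.

Both ratios are ≤ 1 whenever gamma < alpha: fluctuating temperatures always
wire fewer connections than the constant mean temperature, because the warm
phase dominates the integrated development.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .errors import InvalidArgumentError
from .scaling import ScalingParams

__all__ = [
    "CycleSpec",
    "TemperatureProfile",
    "step_cycle_time_fold",
    "step_cycle_connectivity_fold",
    "general_cycle_fold",
    "EXPERIMENTAL_REGIMES",
]

#: The four experimental diurnal regimes, (T_min, T_max) in °C, all with mean 24 °C.
EXPERIMENTAL_REGIMES = {
    "20-28": (20.0, 28.0),
    "18-30": (18.0, 30.0),
    "16-32": (16.0, 32.0),
    "14-34": (14.0, 34.0),
}

TEMP_RANGE_C = (10.0, 35.0)


@dataclass(frozen=True)
class CycleSpec:
    """A symmetric two-level temperature cycle."""

    t_low: float
    t_high: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.t_low) and np.isfinite(self.t_high)):
            raise InvalidArgumentError("cycle temperatures must be finite")
        if self.t_high < self.t_low:
            raise InvalidArgumentError("t_high must be >= t_low")

    @property
    def mean_temp(self) -> float:
        return 0.5 * (self.t_low + self.t_high)

    @property
    def half_amplitude(self) -> float:
        return 0.5 * (self.t_high - self.t_low)


@dataclass(frozen=True)
class TemperatureProfile:
    """A periodic temperature waveform as piecewise-linear segments.

    ``segments`` is a sequence of (duration_hours, temp_start, temp_end);
    durations sum to ``period``.  Build from knots (piecewise-linear with
    wrap-around) via :meth:`from_knots`, or use the factories for the
    canonical shapes.
    """

    segments: tuple[tuple[float, float, float], ...]
    period: float

    def __post_init__(self) -> None:
        if not self.segments:
            raise InvalidArgumentError("profile needs at least one segment")
        total = sum(d for d, _, _ in self.segments)
        if not np.isclose(total, self.period, rtol=1e-9):
            raise InvalidArgumentError(
                f"segment durations sum to {total}, not the period {self.period}"
            )
        for d, t0, t1 in self.segments:
            if d < 0:
                raise InvalidArgumentError("segment durations must be non-negative")
            for t in (t0, t1):
                if not (TEMP_RANGE_C[0] <= t <= TEMP_RANGE_C[1]):
                    raise InvalidArgumentError(
                        f"temperature {t} °C outside the admissible range {TEMP_RANGE_C}"
                    )

    @classmethod
    def from_knots(
        cls, knots: Sequence[tuple[float, float]], period: float
    ) -> "TemperatureProfile":
        """Piecewise-linear waveform through (phase_hours, temp_c) knots, wrapping at the period."""
        if len(knots) < 1:
            raise InvalidArgumentError("need at least one knot")
        times = [k[0] for k in knots]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise InvalidArgumentError("knot times must be strictly increasing")
        if times[0] < 0 or times[-1] >= period:
            raise InvalidArgumentError("knot times must lie within [0, period)")
        segs = []
        for (ta, va), (tb, vb) in zip(knots, knots[1:]):
            segs.append((tb - ta, va, vb))
        # wrap: last knot back to the first across the period boundary
        t_last, v_last = knots[-1]
        t_first, v_first = knots[0]
        # wrap-around segment; any phase offset is immaterial for period averages
        segs.append((period - t_last + t_first, v_last, v_first))
        return cls(segments=tuple(segs), period=period)

    @classmethod
    def constant(cls, temp_c: float, period: float = 24.0) -> "TemperatureProfile":
        return cls(segments=((period, temp_c, temp_c),), period=period)

    @classmethod
    def square(
        cls, t_low: float, t_high: float, period: float = 24.0, duty: float = 0.5
    ) -> "TemperatureProfile":
        """Two-level step cycle: fraction ``duty`` of the period at t_high, the rest at t_low."""
        if not (0.0 < duty < 1.0):
            raise InvalidArgumentError("duty must lie in (0, 1)")
        return cls(
            segments=(
                (duty * period, t_high, t_high),
                ((1.0 - duty) * period, t_low, t_low),
            ),
            period=period,
        )

    @classmethod
    def trapezoid(
        cls,
        t_low: float,
        t_high: float,
        period: float = 24.0,
        hold_hours: float = 8.0,
        ramp_hours: float = 4.0,
    ) -> "TemperatureProfile":
        """The experimental diurnal protocol: hold at the maximum, ramp down,
        hold at the minimum, ramp up (holds and ramps symmetric)."""
        if not np.isclose(2 * (hold_hours + ramp_hours), period, rtol=1e-9):
            raise InvalidArgumentError("2*(hold + ramp) must equal the period")
        return cls(
            segments=(
                (hold_hours, t_high, t_high),
                (ramp_hours, t_high, t_low),
                (hold_hours, t_low, t_low),
                (ramp_hours, t_low, t_high),
            ),
            period=period,
        )

    @classmethod
    def from_csv(cls, path: str | Path, period: float | None = None) -> "TemperatureProfile":
        """Read knots from a CSV with columns (phase_hours, temp_c).

        The period defaults to 24 h unless given.
        """
        knots = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                knots.append((float(row["phase_hours"]), float(row["temp_c"])))
        return cls.from_knots(knots, period if period is not None else 24.0)

    @property
    def mean_temp(self) -> float:
        """Time-weighted mean temperature over one period, °C."""
        num = sum(d * 0.5 * (t0 + t1) for d, t0, t1 in self.segments)
        return num / self.period

    def mean_relative_rate(self, slope: float) -> float:
        """Period average of exp[slope * (T(τ) − mean_temp)].

        On a linear segment the integrand is exponential in τ, so each
        segment integrates in closed form; the quadrature is exact for
        piecewise-linear waveforms (steps included).
        """
        tbar = self.mean_temp
        if slope == 0.0:
            return 1.0
        acc = 0.0
        for d, t0, t1 in self.segments:
            if d == 0.0:
                continue
            a0 = slope * (t0 - tbar)
            a1 = slope * (t1 - tbar)
            if np.isclose(a0, a1, rtol=0, atol=1e-13):
                acc += d * np.exp(0.5 * (a0 + a1))
            else:
                acc += d * (np.exp(a1) - np.exp(a0)) / (a1 - a0)
        return acc / self.period


def step_cycle_time_fold(scaling: ScalingParams, half_amplitude: float) -> float:
    """Developmental-time ratio t̃/t̄ = 1/cosh(alpha ΔT) on a symmetric step cycle."""
    if not (np.isfinite(half_amplitude) and half_amplitude >= 0):
        raise InvalidArgumentError("half_amplitude must be finite and >= 0")
    return 1.0 / np.cosh(scaling.alpha * half_amplitude)


def step_cycle_connectivity_fold(scaling: ScalingParams, half_amplitude: float) -> float:
    """Connectivity ratio ñ/n̄ = [cosh(gamma ΔT)/cosh(alpha ΔT)]^4 on a symmetric step cycle.

    Strictly below 1 for ΔT > 0 whenever gamma < alpha (i.e. beta > 0).
    """
    if not (np.isfinite(half_amplitude) and half_amplitude >= 0):
        raise InvalidArgumentError("half_amplitude must be finite and >= 0")
    return float(
        (np.cosh(scaling.gamma * half_amplitude) / np.cosh(scaling.alpha * half_amplitude)) ** 4
    )


def general_cycle_fold(
    profile: TemperatureProfile,
    scaling: ScalingParams,
    quantity: Literal["time", "connectivity"],
    n_periods: float | None = None,
) -> float:
    """Fold change of a developmental quantity on an arbitrary periodic waveform,
    relative to constant development at the waveform's mean temperature.

    Development spans many periods, so each quantity depends on the waveform
    only through period averages of the relative rate exp[s (T − T̄)]:
    the time ratio is the reciprocal mean relative body rate, and the
    connectivity ratio the fourth power of the brain/body mean-rate quotient.
    Pass ``n_periods`` (periods elapsed before eclosion) to be warned when
    the many-period assumption is doubtful (< 20 periods).
    """
    if n_periods is not None and n_periods < 20:
        warnings.warn(
            f"only {n_periods} periods before completion; phase dependence may not average out",
            RuntimeWarning,
            stacklevel=2,
        )
    r_alpha = profile.mean_relative_rate(scaling.alpha)
    if quantity == "time":
        return 1.0 / r_alpha
    if quantity == "connectivity":
        r_gamma = profile.mean_relative_rate(scaling.gamma)
        return float((r_gamma / r_alpha) ** 4)
    raise InvalidArgumentError(f"quantity must be 'time' or 'connectivity', got {quantity!r}")
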