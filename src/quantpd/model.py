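"""Deterministic forward model for multi-dose PKPD time courses.

A session delivers K bolus doses; each dose k contributes a peak plasma
concentration ``D_k`` at time ``t_k`` and is eliminated exponentially with
half-life ``t_half``.  Tissue effect lags plasma concentration by a fixed
delay ``t_shift`` and follows the sigmoid Emax (Hill) model.  The observed
signal is the drug effect riding on a slowly varying quadratic baseline,

    C(t) = sum_k D_k * u(t - t_shift - t_k) * 2**(-(t - t_shift - t_k)/t_half)
    E(C) = e_max * C**n / (ec50**n + C**n)
    y(t) = a0 + a1*t + a2*t**2 + E(C(t))

with ``u`` the unit step (``u(0) = 1``: a dose takes effect exactly at
``t_k + t_shift`` and the peak ``D_k`` is attained).  Concentrations are in
arbitrary units; EC50 is carried as ``q = log10(ec50)`` during inference so
a uniform prior on ``q`` samples the conventional logarithmic dose axis
evenly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "DoseSchedule",
    "KineticParams",
    "EffectParams",
    "BaselineParams",
    "TimeCourse",
    "plasma_concentration",
    "drug_effect",
    "baseline_signal",
    "model_signal",
    "peak_effect",
    "snr",
]


@dataclass(frozen=True)
class DoseSchedule:
    """Bolus dosing schedule: peak-concentration increments at given times."""

    dose_peaks: tuple[float, ...]
    dose_times: tuple[float, ...]

    def __post_init__(self) -> None:
        peaks = tuple(float(d) for d in self.dose_peaks)
        times = tuple(float(t) for t in self.dose_times)
        object.__setattr__(self, "dose_peaks", peaks)
        object.__setattr__(self, "dose_times", times)
        if len(peaks) != len(times) or len(peaks) < 1:
            raise ValueError("dose_peaks and dose_times must have equal length >= 1")
        if any(not math.isfinite(x) for x in peaks + times):
            raise ValueError("dose schedule must be finite")
        if any(d < 0 for d in peaks):
            raise ValueError("dose_peaks must be nonnegative")
        if any(t < 0 for t in times):
            raise ValueError("dose_times must be nonnegative")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("dose_times must be strictly increasing")


@dataclass(frozen=True)
class KineticParams:
    """Kinetic constants: elimination half-life (min), effect delay (min), Hill n."""

    t_half: float = 41.0
    t_shift: float = 0.5
    hill: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.t_half) and self.t_half > 0):
            raise ValueError("t_half must be positive")
        if not (math.isfinite(self.t_shift) and self.t_shift >= 0):
            raise ValueError("t_shift must be nonnegative")
        if not (math.isfinite(self.hill) and self.hill > 0):
            raise ValueError("hill coefficient must be positive")


@dataclass(frozen=True)
class EffectParams:
    """Sigmoid-Emax parameters.

    ``e_max`` may be negative (drugs that suppress the measured signal);
    EC50 is stored as ``q = log10(ec50)`` which keeps ec50 > 0 by
    construction.
    """

    e_max: float
    q: float

    @property
    def ec50(self) -> float:
        return 10.0 ** self.q

    @classmethod
    def from_ec50(cls, e_max: float, ec50: float) -> "EffectParams":
        if not (ec50 > 0):
            raise ValueError("ec50 must be positive")
        return cls(e_max=float(e_max), q=math.log10(ec50))

    def __post_init__(self) -> None:
        if not (math.isfinite(self.e_max) and math.isfinite(self.q)):
            raise ValueError("effect parameters must be finite")


@dataclass(frozen=True)
class BaselineParams:
    """Quadratic baseline drift B(t) = a0 + a1*t + a2*t**2."""

    a0: float = 0.0
    a1: float = 0.0
    a2: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.a0, self.a1, self.a2):
            if not math.isfinite(v):
                raise ValueError("baseline coefficients must be finite")


@dataclass
class TimeCourse:
    """A sampled time-signal curve (minutes vs arbitrary signal units)."""

    times: NDArray[np.float64]
    values: NDArray[np.float64]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-d arrays of equal length")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.values))):
            raise ValueError("time course must not contain missing/non-finite values")
        if self.times.size and self.times[0] < 0:
            raise ValueError("times must be nonnegative")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


def plasma_concentration(
    t: ArrayLike, schedule: DoseSchedule, kin: KineticParams
) -> NDArray[np.float64] | float:
    """Plasma concentration from superposed, exponentially eliminated boluses.

    Each dose contributes ``D_k * 2**(-(t - t_shift - t_k)/t_half)`` from
    ``t = t_k + t_shift`` onwards (inclusive) and nothing before.
    """
    t_arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("t must be finite")
    lag = t_arr[..., None] - kin.t_shift - np.asarray(schedule.dose_times)
    with np.errstate(over="ignore"):
        decay = np.where(lag >= 0, np.exp2(-np.abs(lag) / kin.t_half), 0.0)
    conc = decay @ np.asarray(schedule.dose_peaks)
    return conc if t_arr.ndim else float(conc)


def drug_effect(
    c: ArrayLike, eff: EffectParams, hill: float = 1.0
) -> NDArray[np.float64] | float:
    """Sigmoid Emax effect E(C) = e_max * C^n / (ec50^n + C^n)."""
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0):
        raise ValueError("concentration must be nonnegative")
    if not (hill > 0):
        raise ValueError("hill coefficient must be positive")
    cn = c_arr**hill
    out = eff.e_max * cn / (eff.ec50**hill + cn)
    return out if c_arr.ndim else float(out)


def baseline_signal(
    t: ArrayLike, b: BaselineParams
) -> NDArray[np.float64] | float:
    """Quadratic baseline drift evaluated at t."""
    t_arr = np.asarray(t, dtype=float)
    out = b.a0 + b.a1 * t_arr + b.a2 * t_arr**2
    return out if t_arr.ndim else float(out)


def model_signal(
    t: ArrayLike,
    schedule: DoseSchedule,
    kin: KineticParams,
    eff: EffectParams,
    b: BaselineParams,
) -> NDArray[np.float64] | float:
    """Full forward model: baseline drift plus drug effect, B(t) + E(C(t))."""
    c = plasma_concentration(t, schedule, kin)
    return baseline_signal(t, b) + drug_effect(c, eff, kin.hill)


def _effect_grid(
    schedule: DoseSchedule,
    kin: KineticParams,
    window: tuple[float, float],
    dt: float,
) -> NDArray[np.float64]:
    t_lo, t_hi = float(window[0]), float(window[1])
    if not t_hi > t_lo:
        raise ValueError("window must satisfy t_hi > t_lo")
    grid = np.arange(t_lo, t_hi + dt / 2, dt)
    # C is piecewise monotone; its local maxima sit exactly at dose onsets,
    # so include those points regardless of grid phase.
    onsets = np.asarray(schedule.dose_times) + kin.t_shift
    onsets = onsets[(onsets >= t_lo) & (onsets <= t_hi)]
    return np.union1d(grid, onsets)


def peak_effect(
    schedule: DoseSchedule,
    kin: KineticParams,
    eff: EffectParams,
    window: tuple[float, float] = (0.0, 40.0),
    dt: float = 0.01,
) -> float:
    """Maximum noise-free drug effect over a time window.

    Evaluated on a dense grid (default 0.01-min spacing) augmented with the
    exact dose-onset times where the concentration peaks.
    """
    t = _effect_grid(schedule, kin, window, dt)
    c = plasma_concentration(t, schedule, kin)
    return float(np.max(drug_effect(c, eff, kin.hill)))


def snr(
    schedule: DoseSchedule,
    kin: KineticParams,
    eff: EffectParams,
    noise_sd: float,
    window: tuple[float, float] = (0.0, 40.0),
) -> float:
    """Signal-to-noise ratio: peak noise-free drug effect over the noise SD."""
    if not (noise_sd > 0):
        raise ValueError("noise_sd must be positive")
    return peak_effect(schedule, kin, eff, window) / float(noise_sd)
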