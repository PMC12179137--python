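"""Piecewise-exponential circadian blood-pressure curves.

The day is split into three phases by a wake time ``t1`` and a bedtime
``t2`` (decimal hours after midnight).  During the wake phase pressure
rises exponentially from a nocturnal baseline ``base`` toward a daytime
plateau ``base + incr``; after bedtime it decays back toward ``base`` at
the same rate ``k`` (per hour).  The *extended* variant lets the pre-wake
segment of a day decay from the previous day's ``base``/``incr`` instead
of its own, assigning the sleep phase before waking to the previous
physiological day.

All evaluation here is closed-form and deterministic; fitting lives in
:mod:`circabp.fitting`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "PrevDayCarry",
    "Phase",
    "classify_phase",
    "eval_basic",
    "eval_extended",
    "eval_profile",
    "daytime_plateau",
    "nocturnal_trough",
]


class Phase(str, enum.Enum):
    """Which branch of the piecewise model a clock time falls in."""

    WAKE = "wake"
    POST_BED = "post_bed"
    PRE_WAKE = "pre_wake"


@dataclass(frozen=True)
class ModelParams:
    """The five quantities fitted per subject-day-channel.

    Parameters
    ----------
    base : float
        Nocturnal baseline pressure (mmHg); must be positive.
    incr : float
        Amplitude of the daytime rise above ``base`` (mmHg); non-negative.
        ``base + incr`` is the daytime plateau.
    k : float
        Exponential rate constant of both the morning rise and the
        evening/overnight decay (per hour); positive.
    t1 : float
        Wake time, hours after midnight; ``0 < t1 < t2``.
    t2 : float
        Bedtime, hours after midnight; may exceed 24 for bedtimes past
        midnight (bounded at 25 under the default fitting limits).
    """

    base: float
    incr: float
    k: float
    t1: float
    t2: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.base, self.incr, self.k, self.t1, self.t2]).all():
            raise ValueError("model parameters must be finite")
        if self.base <= 0:
            raise ValueError(f"base must be positive, got {self.base}")
        if self.incr < 0:
            raise ValueError(f"incr must be non-negative, got {self.incr}")
        if self.k <= 0:
            raise ValueError(f"k must be positive, got {self.k}")
        if not 0 < self.t1 < self.t2:
            raise ValueError(f"need 0 < t1 < t2, got t1={self.t1}, t2={self.t2}")

    def as_array(self) -> np.ndarray:
        return np.array([self.base, self.incr, self.k, self.t1, self.t2])


@dataclass(frozen=True)
class PrevDayCarry:
    """Previous day's baseline and amplitude, carried into the pre-wake
    segment by the extended model."""

    base_prev: float
    incr_prev: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.base_prev, self.incr_prev]).all():
            raise ValueError("carry values must be finite")
        if self.base_prev <= 0:
            raise ValueError(f"base_prev must be positive, got {self.base_prev}")
        if self.incr_prev < 0:
            raise ValueError(f"incr_prev must be non-negative, got {self.incr_prev}")


def _check_time(t: float) -> None:
    if not 0 <= t < 24:
        raise ValueError(f"t must lie in [0, 24), got {t}")


def classify_phase(params: ModelParams, t: float) -> Phase:
    """Assign clock time ``t`` (hours in [0, 24)) to a model phase.

    Boundaries are half-open: pre-wake is ``[0, t1)``, wake is
    ``[t1, min(t2, 24))`` and post-bed is ``[t2, 24)`` — so every time
    belongs to exactly one phase, and both closures agree with the
    neighbouring branch by continuity.  When ``t2 >= 24`` the post-bed
    branch is unreachable within the day.
    """
    _check_time(t)
    if t < params.t1:
        return Phase.PRE_WAKE
    if t < min(params.t2, 24.0):
        return Phase.WAKE
    return Phase.POST_BED


def _night_amplitude(params: ModelParams) -> float:
    # Amplitude reached by bedtime, from which the overnight decay starts.
    return params.incr * -np.expm1(-params.k * (params.t2 - params.t1))


def eval_basic(params: ModelParams, t: float) -> float:
    """Evaluate the basic model at clock time ``t`` (hours in [0, 24)).

    Wake phase: ``base + incr*(1 - exp(-k*(t - t1)))``.
    Post-bed (until midnight): the bedtime value decays as
    ``exp(-k*(t - t2))``.
    Pre-wake (between midnight and waking): the decay continues with
    elapsed time ``tau = max(t + 24 - t2, 0)``; the clamp keeps the
    exponent non-positive when bedtime passes midnight (``t2 > 24``).

    The result always lies in ``[base, base + incr]``.
    """
    phase = classify_phase(params, t)
    if phase is Phase.WAKE:
        return params.base + params.incr * -np.expm1(-params.k * (t - params.t1))
    if phase is Phase.POST_BED:
        return params.base + _night_amplitude(params) * np.exp(-params.k * (t - params.t2))
    tau = max(t + 24.0 - params.t2, 0.0)
    return params.base + _night_amplitude(params) * np.exp(-params.k * tau)


def eval_extended(params: ModelParams, carry: PrevDayCarry, t: float) -> float:
    """Evaluate the extended model: identical to :func:`eval_basic` except
    the pre-wake decay starts from the previous day's ``base``/``incr``
    (``carry``); the rate ``k`` and the times ``t1``/``t2`` are the current
    day's."""
    phase = classify_phase(params, t)
    if phase is not Phase.PRE_WAKE:
        return eval_basic(params, t)
    tau = max(t + 24.0 - params.t2, 0.0)
    amp = carry.incr_prev * -np.expm1(-params.k * (params.t2 - params.t1))
    return carry.base_prev + amp * np.exp(-params.k * tau)


def eval_profile(
    day_params: Sequence[ModelParams],
    variant: str,
    times: Iterable[tuple[int, float]],
) -> list[float]:
    """Evaluate a multi-day profile at ``(day_index, hour)`` points.

    ``variant`` is ``"basic"`` or ``"extended"``.  For the extended
    variant, day ``d`` carries day ``d-1``'s (base, incr); day 0 uses its
    own, which reduces its pre-wake segment to the basic formula.
    """
    if variant not in ("basic", "extended"):
        raise ValueError(f"unknown variant {variant!r}")
    day_params = list(day_params)
    out = []
    for day, t in times:
        if not 0 <= day < len(day_params):
            raise IndexError(f"day index {day} out of range for {len(day_params)} days")
        p = day_params[day]
        if variant == "basic":
            out.append(eval_basic(p, t))
        else:
            prev = day_params[day - 1] if day > 0 else p
            out.append(eval_extended(p, PrevDayCarry(prev.base, prev.incr), t))
    return out


def daytime_plateau(params: ModelParams) -> float:
    """Limiting wake-phase pressure as ``k*(t - t1)`` grows large:
    ``base + incr*(1 - e^{-k*T})`` with the rise complete."""
    return params.base + params.incr * -np.expm1(-params.k * 1e6)


def nocturnal_trough(params: ModelParams) -> float:
    """Limiting night-time pressure once the post-bed decay completes:
    the bedtime amplitude multiplied down by ``e^{-k*tau}`` as ``tau``
    grows, leaving ``base``."""
    return params.base + _night_amplitude(params) * np.exp(-params.k * 1e6)


# ---------------------------------------------------------------------------
# Vectorised evaluation (used by the fitting objective and by plotting).
# ---------------------------------------------------------------------------

def shape_function(t: np.ndarray, k: float, t1: float, t2: float) -> np.ndarray:
    """Dimensionless profile g(t) with 0 <= g <= 1 such that the basic
    prediction is ``base + incr * g(t)``.  Vectorised over ``t``."""
    t = np.asarray(t, dtype=float)
    night_amp = -np.expm1(-k * (t2 - t1))
    wake = (t >= t1) & (t < min(t2, 24.0))
    post = t >= min(t2, 24.0)
    g = np.empty_like(t)
    g[wake] = -np.expm1(-k * (t[wake] - t1))
    g[post] = night_amp * np.exp(-k * (t[post] - t2))
    pre = ~(wake | post)
    tau = np.maximum(t[pre] + 24.0 - t2, 0.0)
    g[pre] = night_amp * np.exp(-k * tau)
    return g


def predict(
    t: np.ndarray,
    base: float,
    incr: float,
    k: float,
    t1: float,
    t2: float,
    carry: PrevDayCarry | None = None,
) -> np.ndarray:
    """Vectorised model prediction at times ``t`` (hours in [0, 24)).

    With ``carry`` given, pre-wake points use the carried base/incr
    (extended model); otherwise all points use the day's own (basic).
    """
    t = np.asarray(t, dtype=float)
    g = shape_function(t, k, t1, t2)
    pred = base + incr * g
    if carry is not None:
        pre = t < t1
        if pre.any():
            night_amp = -np.expm1(-k * (t2 - t1))
            tau = np.maximum(t[pre] + 24.0 - t2, 0.0)
            pred[pre] = carry.base_prev + carry.incr_prev * night_amp * np.exp(-k * tau)
    return pred
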