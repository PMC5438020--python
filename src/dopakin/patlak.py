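"""Reference-tissue Patlak graphical analysis.

For an irreversibly trapped tracer, plotting

    y(t) = C_target(t) / C_ref(t)   against   x(t) = ∫0^t C_ref / C_ref(t)

becomes linear once the reversible compartments have equilibrated; the
late-time slope is the influx constant relative to the reference region,
Ki_cer (min⁻¹), the index of dopamine synthesis capacity. The fit is an
ordinary least-squares line over the frames whose mid-times lie at or
beyond ``t_star``; the x-axis integral uses the step-function (frame-mean)
reconstruction of the curve, which is exact for constant inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import (
    DegenerateReferenceError,
    DomainError,
    InsufficientDataError,
    ScheduleError,
)
from .simulate import TimeActivityCurve

__all__ = ["PatlakFit", "SuvValue", "cumulative_integral", "patlak_reference", "suv_at"]


@dataclass(frozen=True)
class PatlakFit:
    """Result of a reference-tissue Patlak fit.

    ki_cer : slope, min⁻¹ (the influx constant)
    intercept : dimensionless
    t_star : start of the linear window, minutes
    n_points : frames used in the fit
    r_squared : coefficient of determination of the line
    residuals : per-point y residuals
    x, y : the fitted Patlak coordinates
    weighted : whether frame-duration weights were applied
    """

    ki_cer: float
    intercept: float
    t_star: float
    n_points: int
    r_squared: float
    residuals: np.ndarray
    x: np.ndarray
    y: np.ndarray
    weighted: bool = False

    def to_dict(self) -> dict:
        return {
            "ki_cer": self.ki_cer,
            "intercept": self.intercept,
            "t_star": self.t_star,
            "n_points": self.n_points,
            "r_squared": self.r_squared,
            "weighted": self.weighted,
            "points": [
                {"x": float(xi), "y": float(yi), "residual": float(ri)}
                for xi, yi, ri in zip(self.x, self.y, self.residuals)
            ],
        }


@dataclass(frozen=True)
class SuvValue:
    """Standardized uptake value at a stated time (dimensionless)."""

    value: float
    at_time: float


def cumulative_integral(tac: TimeActivityCurve) -> np.ndarray:
    """Running integral of the TAC at frame mid-times (kBq·ml⁻¹·min).

    The frame-mean activity is held constant over each frame (step-function
    reconstruction), so the integral to a frame's mid-time is the sum of all
    earlier frames plus half the current frame's contribution.
    """
    contrib = tac.activity * tac.schedule.duration_min
    return np.cumsum(contrib) - 0.5 * contrib


def patlak_reference(
    target: TimeActivityCurve,
    reference: TimeActivityCurve,
    t_star: float = 24.0,
    weighted: bool = False,
) -> PatlakFit:
    """Fit the reference-tissue Patlak line and return the slope as Ki_cer.

    Both curves must share a schedule; the fit uses frames with mid-time
    >= ``t_star`` minutes (at least 3), requiring strictly positive
    reference activity there. ``weighted=True`` applies frame-duration
    weights to the least-squares fit.
    """
    if len(target.schedule) != len(reference.schedule) or not np.allclose(
        target.schedule.start_s, reference.schedule.start_s
    ) or not np.allclose(target.schedule.duration_s, reference.schedule.duration_s):
        raise ScheduleError("target and reference curves must share a frame schedule")
    sched = target.schedule
    if not 0 <= t_star <= sched.total_min:
        raise DomainError(f"t_star {t_star} min outside the scan (0..{sched.total_min} min)")

    mask = sched.mid_min >= t_star
    if mask.sum() < 3:
        raise InsufficientDataError(
            f"only {int(mask.sum())} frames at or after t* = {t_star} min; need >= 3"
        )
    ref_late = reference.activity[mask]
    if np.any(ref_late <= 0):
        raise DegenerateReferenceError("reference activity must be > 0 in the fit window")

    x = cumulative_integral(reference)[mask] / ref_late
    y = target.activity[mask] / ref_late

    if weighted:
        w = sched.duration_min[mask]
        wx, wy = np.average(x, weights=w), np.average(y, weights=w)
        slope = np.sum(w * (x - wx) * (y - wy)) / np.sum(w * (x - wx) ** 2)
        intercept = wy - slope * wx
    else:
        slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    resid = y - fitted
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - np.sum(resid**2) / ss_tot)
    return PatlakFit(
        ki_cer=float(slope),
        intercept=float(intercept),
        t_star=float(t_star),
        n_points=int(mask.sum()),
        r_squared=float(min(r2, 1.0)),
        residuals=resid,
        x=x,
        y=y,
        weighted=weighted,
    )


def suv_at(tac: TimeActivityCurve, t: float, injected_mbq: float, weight_kg: float) -> SuvValue:
    """Standardized uptake value of the frame containing time ``t`` (min).

    SUV = activity (kBq·ml⁻¹) / (injected activity / body weight), with the
    usual 1 g = 1 ml tissue convention, so the normalizer is
    ``injected_mbq / weight_kg`` in kBq·ml⁻¹.
    """
    if injected_mbq <= 0 or weight_kg <= 0:
        raise DomainError("injected activity and body weight must be positive")
    sched = tac.schedule
    if not sched.start_min[0] <= t <= sched.total_min:
        raise DomainError(f"time {t} min outside the scan")
    idx = int(np.searchsorted(sched.end_min, t, side="left"))
    idx = min(idx, len(sched) - 1)
    normalizer = injected_mbq / weight_kg  # MBq/kg == kBq/g == kBq/ml
    return SuvValue(value=float(tac.activity[idx] / normalizer), at_time=float(t))
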