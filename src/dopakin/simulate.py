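"""Time–activity curve simulation.

The simulator produces region-level dynamic-PET time–activity curves (TACs)
from an irreversible two-tissue compartment model driven by a synthetic
arterial input. The free compartment receives tracer at rate ``K1``
(ml·min⁻¹·ml⁻¹) and clears at ``k2 + k3`` (min⁻¹); the trapped compartment
is fed irreversibly from the free compartment at ``k3``. A reference region
is the same model with ``k3 = 0`` (no specific trapping). All activities
are treated as decay-corrected, so no physical-decay term appears.

The arterial input is a linear-rise/tri-exponential (Feng-type) curve

    Cp(t) = (A1·τ − A2 − A3)·e^{−λ1 τ} + A2·e^{−λ2 τ} + A3·e^{−λ3 τ},

with τ = t − delay and Cp = 0 before the injection delay. It starts at
zero, peaks within the first minutes and decays thereafter; it exists only
to drive the simulator (the downstream graphical analysis never sees it —
that is the point of a reference-tissue method).

Frame values are the time-average of the instantaneous model curve over
each frame, the quantity a scanner reports. Optional Gaussian noise has
standard deviation ``noise_scale · sqrt(max(C, eps) / duration_min)``, the
standard count-statistics weighting assumption for dynamic PET.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import fftconvolve

from .errors import DomainError
from .schedules import FrameSchedule

__all__ = [
    "PlasmaInputParams",
    "RegionKinetics",
    "TimeActivityCurve",
    "plasma_input",
    "tissue_curve",
    "simulate_region",
    "DEFAULT_PLASMA",
    "DEFAULT_STRIATUM",
    "DEFAULT_REFERENCE",
]

#: time step (minutes) of the internal simulation grid
_DT_MIN = 0.01
#: variance floor (kBq·ml⁻¹) for the activity-dependent noise model
_NOISE_EPS = 1e-3


@dataclass(frozen=True)
class PlasmaInputParams:
    """Feng-type arterial input: amplitudes (kBq·ml⁻¹·min⁻¹ for the linear
    term, kBq·ml⁻¹ for the exponential terms), eigenvalues (min⁻¹) and an
    injection delay (min)."""

    a1: float = 200.0
    a2: float = 6.0
    a3: float = 5.0
    lam1: float = 4.0
    lam2: float = 0.12
    lam3: float = 0.01
    delay_min: float = 0.5

    def __post_init__(self) -> None:
        if min(self.a1, self.a2, self.a3) < 0 or min(self.lam1, self.lam2, self.lam3) <= 0:
            raise DomainError("plasma-input amplitudes must be >= 0 and eigenvalues > 0")
        if self.delay_min < 0:
            raise DomainError("injection delay must be >= 0")


@dataclass(frozen=True)
class RegionKinetics:
    """Compartmental rate constants of one region.

    K1 : delivery, ml·min⁻¹·ml⁻¹, > 0
    k2 : washout, min⁻¹, >= 0 (0 = no washout: all delivered tracer is
         retained, the saturated limit of the k3 sensitivity analysis)
    k3 : irreversible trapping (AADC-mediated conversion), min⁻¹, >= 0.
         ``k3 = 0`` gives a trapping-free reference region.
    """

    K1: float
    k2: float
    k3: float = 0.0

    def __post_init__(self) -> None:
        if self.K1 <= 0 or self.k2 < 0 or self.k3 < 0:
            raise DomainError("require K1 > 0, k2 >= 0, k3 >= 0")


#: default striatal and cerebellar (reference) kinetics used by the examples
DEFAULT_STRIATUM = RegionKinetics(K1=0.04, k2=0.08, k3=0.02)
DEFAULT_REFERENCE = RegionKinetics(K1=0.04, k2=0.08, k3=0.0)
DEFAULT_PLASMA = PlasmaInputParams()


@dataclass(frozen=True)
class TimeActivityCurve:
    """Per-frame mean activity concentration (kBq·ml⁻¹) on a schedule."""

    schedule: FrameSchedule
    activity: np.ndarray
    region_label: str = ""

    def __post_init__(self) -> None:
        act = np.asarray(self.activity, dtype=float)
        object.__setattr__(self, "activity", act)
        if act.ndim != 1 or act.size != len(self.schedule):
            raise DomainError("activity length must equal the frame count")


def plasma_input(params: PlasmaInputParams, t_min):
    """Arterial tracer concentration (kBq·ml⁻¹) at time(s) ``t_min`` (min).

    Zero before the injection delay; non-negative for all t >= 0.
    """
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise DomainError("plasma_input requires t >= 0")
    tau = t - params.delay_min
    rising = np.maximum(tau, 0.0)
    c = (
        (params.a1 * rising - params.a2 - params.a3) * np.exp(-params.lam1 * rising)
        + params.a2 * np.exp(-params.lam2 * rising)
        + params.a3 * np.exp(-params.lam3 * rising)
    )
    c = np.where(tau < 0, 0.0, c)
    return c if c.ndim else float(c)


def tissue_curve(kin: RegionKinetics, input_params: PlasmaInputParams, t_min: np.ndarray) -> np.ndarray:
    """Instantaneous tissue concentration C_free + C_trapped on a uniform grid.

    Solves the irreversible two-tissue model by trapezoid-corrected FFT
    convolution of the input with the ``exp(-(k2+k3) t)`` kernel; the trapped
    compartment is the running integral of ``k3 · C_free``. ``t_min`` must be
    a uniform, ascending grid starting at 0.
    """
    t = np.asarray(t_min, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise DomainError("need a grid of at least two time points")
    dt = t[1] - t[0]
    if not np.allclose(np.diff(t), dt, rtol=1e-6):
        raise DomainError("tissue_curve requires a uniform time grid")
    cp = np.asarray(plasma_input(input_params, t))
    kernel = np.exp(-(kin.k2 + kin.k3) * t)
    # trapezoid-corrected discrete convolution (Cp[0] == 0, kernel[0] == 1)
    conv = fftconvolve(cp, kernel)[: t.size]
    c_free = kin.K1 * dt * (conv - 0.5 * cp - 0.5 * cp[0] * kernel)
    c_free = np.maximum(c_free, 0.0)
    if kin.k3 == 0.0:
        return c_free
    c_trap = kin.k3 * cumulative_trapezoid(c_free, t, initial=0.0)
    return c_free + c_trap


def _frame_means(curve: np.ndarray, t: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Average the instantaneous curve over each frame (exact on the grid)."""
    running = cumulative_trapezoid(curve, t, initial=0.0)
    at_start = np.interp(schedule.start_min, t, running)
    at_end = np.interp(schedule.end_min, t, running)
    return (at_end - at_start) / schedule.duration_min


def simulate_region(
    kin: RegionKinetics,
    input_params: PlasmaInputParams,
    schedule: FrameSchedule,
    noise_scale: float = 0.0,
    seed: int | None = None,
    region_label: str = "",
) -> TimeActivityCurve:
    """Simulate the frame-averaged TAC of one region.

    ``noise_scale`` scales zero-mean Gaussian frame noise with standard
    deviation ``noise_scale · sqrt(max(C, eps)/duration_min)``; 0 gives the
    noiseless model curve. The same ``seed`` always reproduces the same TAC.
    """
    if noise_scale < 0:
        raise DomainError("noise_scale must be >= 0")
    t = np.arange(0.0, schedule.total_min + _DT_MIN, _DT_MIN)
    curve = tissue_curve(kin, input_params, t)
    means = _frame_means(curve, t, schedule)
    if noise_scale > 0:
        rng = np.random.default_rng(seed)
        sd = noise_scale * np.sqrt(np.maximum(means, _NOISE_EPS) / schedule.duration_min)
        means = means + rng.normal(0.0, sd)
    return TimeActivityCurve(schedule=schedule, activity=means, region_label=region_label)
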