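"""Dynamic-PET frame schedules.

A frame schedule is the ordered list of acquisition frames of a dynamic
scan, each with a start time and a duration. Frames are contiguous and
non-overlapping and the first frame starts at 0 s. Times are stored in
seconds (the unit of the acquisition protocol and of the on-disk CSV);
kinetic computations use minutes via the ``*_min`` accessors.

Two presets ship with the package, the 26-frame and 32-frame protocols of
the two ECAT scanners the simulated study designs emulate::

    study1_26f : 1x30 s, 4x60 s, 3x120 s, 3x180 s, 15x300 s   (94.5 min)
    study2_32f : 8x15 s, 3x60 s, 5x120 s, 16x300 s            (95 min)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SpecificationError

__all__ = ["FrameSchedule", "make_schedule", "SCHEDULE_PRESETS", "get_preset"]

#: Named frame-composition presets, as (count, duration_s) run-length specs.
SCHEDULE_PRESETS: dict[str, list[tuple[int, float]]] = {
    "study1_26f": [(1, 30), (4, 60), (3, 120), (3, 180), (15, 300)],
    "study2_32f": [(8, 15), (3, 60), (5, 120), (16, 300)],
}


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping frame grid of a dynamic scan.

    Parameters
    ----------
    start_s : array of frame start times, seconds
    duration_s : array of frame durations, seconds
    """

    start_s: np.ndarray
    duration_s: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.start_s, dtype=float)
        dur = np.asarray(self.duration_s, dtype=float)
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "duration_s", dur)
        if start.ndim != 1 or start.shape != dur.shape or start.size == 0:
            raise SpecificationError("schedule needs matching, non-empty start/duration arrays")
        if np.any(dur <= 0):
            raise SpecificationError("frame durations must be positive")
        if start[0] < 0:
            raise SpecificationError("first frame must start at t >= 0")
        if start.size > 1 and not np.allclose(start[1:], start[:-1] + dur[:-1], atol=1e-9):
            raise SpecificationError("frames must be contiguous and non-overlapping")

    def __len__(self) -> int:
        return int(self.start_s.size)

    @property
    def end_s(self) -> np.ndarray:
        return self.start_s + self.duration_s

    @property
    def total_s(self) -> float:
        """Total scan duration in seconds (= end of the last frame)."""
        return float(self.end_s[-1])

    @property
    def mid_s(self) -> np.ndarray:
        return self.start_s + self.duration_s / 2.0

    # minute-scale accessors used by all kinetic computations
    @property
    def start_min(self) -> np.ndarray:
        return self.start_s / 60.0

    @property
    def duration_min(self) -> np.ndarray:
        return self.duration_s / 60.0

    @property
    def end_min(self) -> np.ndarray:
        return self.end_s / 60.0

    @property
    def mid_min(self) -> np.ndarray:
        return self.mid_s / 60.0

    @property
    def total_min(self) -> float:
        return self.total_s / 60.0


def make_schedule(spec: list[tuple[int, float]]) -> FrameSchedule:
    """Build a contiguous schedule from a run-length spec.

    ``spec`` is a list of ``(count, duration_s)`` pairs, e.g. the 32-frame
    protocol ``[(8, 15), (3, 60), (5, 120), (16, 300)]``. The schedule starts
    at 0 and contains ``sum(count)`` frames.
    """
    if not spec:
        raise SpecificationError("empty schedule specification")
    durations: list[float] = []
    for i, (count, dur) in enumerate(spec):
        if int(count) != count or count < 1:
            raise SpecificationError(f"spec entry {i}: count must be a positive integer")
        if dur <= 0:
            raise SpecificationError(f"spec entry {i}: duration must be positive")
        durations.extend([float(dur)] * int(count))
    dur_arr = np.array(durations)
    start = np.concatenate([[0.0], np.cumsum(dur_arr)[:-1]])
    return FrameSchedule(start_s=start, duration_s=dur_arr)


def get_preset(name: str) -> FrameSchedule:
    """Return a named preset schedule (``study1_26f`` or ``study2_32f``)."""
    try:
        spec = SCHEDULE_PRESETS[name]
    except KeyError:
        known = ", ".join(sorted(SCHEDULE_PRESETS))
        raise SpecificationError(f"unknown schedule preset {name!r} (known: {known})") from None
    return make_schedule(spec)
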