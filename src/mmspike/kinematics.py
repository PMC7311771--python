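"""Scalar speed waveforms and cumulative head excursion from 6-DOF parameters.

The three translation channels are collapsed into one linear speed (mm/s) by
taking the Euclidean norm of the framewise difference vector divided by the
sampling interval — the standard framewise-displacement construction; the
rotational analogue yields angular speed in deg/s.  Accumulating speed x dt
gives the head excursion: the net path length of displacement (mm) or
rotation (deg) over the scan, the physical-motion summary the effect-size
analysis runs on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mmspike.errors import ValidationError
from mmspike.motion_io import MotionTrace

__all__ = ["SpeedSeries", "Excursion", "linear_speed", "angular_speed", "head_excursion"]

DEG_TO_RAD = np.pi / 180.0


@dataclass(frozen=True)
class SpeedSeries:
    """Uniformly sampled non-negative scalar speed waveform.

    ``kind`` is ``"linear"`` (mm/s) or ``"angular"`` (deg/s); length is one
    less than the source trace's frame count (finite differencing).
    """

    subject_id: str
    kind: str
    dt: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "angular"):
            raise ValidationError(f"kind must be linear|angular, got {self.kind!r}")
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValidationError("speed values must be 1-D")
        if not np.all(np.isfinite(vals)):
            raise ValidationError("speed values must be finite")
        if np.any(vals < 0):
            raise ValidationError("speed values must be non-negative")
        if not (np.isfinite(self.dt) and self.dt > 0):
            raise ValidationError(f"dt must be positive, got {self.dt}")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return self.values.size

    def replace_values(self, values: np.ndarray) -> "SpeedSeries":
        return SpeedSeries(self.subject_id, self.kind, self.dt, values)


@dataclass(frozen=True)
class Excursion:
    """Cumulative path length per subject: linear in mm, angular in degrees."""

    subject_id: str
    linear_pathlength: float
    angular_pathlength: float


def _framewise_speed(channels: np.ndarray, dt: float, combine: str) -> np.ndarray:
    diffs = np.diff(channels, axis=0)
    if combine == "euclidean":
        mag = np.linalg.norm(diffs, axis=1)
    elif combine == "sum_abs":
        mag = np.abs(diffs).sum(axis=1)
    else:
        raise ValidationError(f"unknown combine rule {combine!r}")
    return mag / dt


def linear_speed(trace: MotionTrace, combine: str = "euclidean") -> SpeedSeries:
    """Linear speed (mm/s): norm of the framewise translation difference / dt."""
    if trace.n_frames < 2:
        raise ValidationError("need at least 2 frames to differentiate")
    return SpeedSeries(
        subject_id=trace.subject_id,
        kind="linear",
        dt=trace.dt,
        values=_framewise_speed(trace.translations, trace.dt, combine),
    )


def angular_speed(
    trace: MotionTrace, combine: str = "euclidean", unit: str = "deg"
) -> SpeedSeries:
    """Angular speed: norm of the framewise rotation difference / dt.

    Internally degrees per second; ``unit="rad"`` applies the pure display
    conversion pi/180 (scale-invariant statistics downstream are unaffected,
    excursion magnitudes are).
    """
    if trace.n_frames < 2:
        raise ValidationError("need at least 2 frames to differentiate")
    vals = _framewise_speed(trace.rotations, trace.dt, combine)
    if unit == "rad":
        vals = vals * DEG_TO_RAD
    elif unit != "deg":
        raise ValidationError(f"unit must be deg|rad, got {unit!r}")
    return SpeedSeries(
        subject_id=trace.subject_id, kind="angular", dt=trace.dt, values=vals
    )


def head_excursion(speed: SpeedSeries) -> float:
    """Cumulative path length: sum of speed x dt (mm or deg by kind)."""
    return float(np.sum(speed.values) * speed.dt)
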