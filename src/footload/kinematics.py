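"""Segment orientation and vertical acceleration in the sagittal plane.

Each sensor's local frame has ``x`` along the medio-lateral pitch axis and
``y``/``z`` spanning the sagittal plane.  Two frame conventions are used:

* **foot**: ``z`` is the sole normal, so the tilt angle ``theta`` (measured
  from horizontal) is zero when the foot is flat; the vertical component of a
  sensor-frame acceleration is ``az*cos(theta) - ay*sin(theta)``.
* **long segments** (thigh, shank, and the sacrum-mounted trunk sensor):
  ``z`` runs along the segment's long axis, so ``theta`` is pi/2 when the
  segment is vertical; the vertical component is
  ``az*sin(theta) - ay*cos(theta)``.

These are the only conventions under which the two transforms reduce to the
correct static limits (flat foot reads gravity on ``z``; a vertical shank
reads gravity along its long axis).

Tilt is initialized from the gravity direction during the initial stationary
interval and propagated by trapezoidal integration of the pitch-rate gyro
channel.  The whole-body load model downstream works with *dynamic*
(gravity-free) accelerations, so sensor accelerations are expected to have
had their static offsets removed before the vertical transforms are applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .io_formats import DataError, ImuRecording, ParameterError

__all__ = [
    "SegmentOrientation",
    "static_tilt",
    "integrate_gyro",
    "integrate_pitch",
    "vertical_accel_foot",
    "vertical_accel_long_segment",
]

#: segment kinds keyed by segment_id prefix
FOOT_KIND = "foot"
LONG_KIND = "long"


@dataclass
class SegmentOrientation:
    """Sagittal-plane tilt angle series (rad) of one segment."""

    theta: np.ndarray
    theta0: float


def segment_kind(segment_id: str) -> str:
    return FOOT_KIND if segment_id.startswith("foot") else LONG_KIND


def static_tilt(
    rec: ImuRecording, window_s: float = 1.0, kind: str | None = None, g: float = 9.8
) -> float:
    """Initial tilt angle from the gravity direction during the static window.

    At rest the accelerometer reads the gravity reaction; its direction in the
    sensor's sagittal (y, z) plane fixes the tilt.  For a foot sensor at tilt
    ``theta`` the static reading is ``(-g sin(theta), g cos(theta))``, for a
    long segment ``(-g cos(theta), g sin(theta))``.
    """
    kind = kind or segment_kind(rec.segment_id)
    n = int(round(window_s * rec.fs))
    if n < 1 or n > rec.n:
        raise ParameterError("static window does not fit the recording")
    ay = float(np.mean(rec.acc[:n, 1]))
    az = float(np.mean(rec.acc[:n, 2]))
    gmag = float(np.hypot(ay, az))
    if gmag < 0.5 * g:
        raise DataError(
            f"{rec.segment_id}: static gravity magnitude {gmag:.2f} m/s^2 is "
            "implausibly small; sensor not static or miscalibrated"
        )
    if kind == FOOT_KIND:
        return float(np.arctan2(-ay, az))
    return float(np.arctan2(az, -ay))


def integrate_pitch(t: np.ndarray, omega_x: np.ndarray, theta0: float) -> SegmentOrientation:
    """Tilt series from the pitch-rate gyro channel, trapezoidal rule."""
    t = np.asarray(t, dtype=float)
    omega_x = np.asarray(omega_x, dtype=float)
    if t.shape != omega_x.shape:
        raise ParameterError("time and angular-velocity series must have equal length")
    theta = theta0 + cumulative_trapezoid(omega_x, t, initial=0.0)
    return SegmentOrientation(theta=theta, theta0=theta0)


def integrate_gyro(rec: ImuRecording, theta0: float) -> SegmentOrientation:
    """Tilt series of a recording; the pitch axis is the local x gyro channel."""
    return integrate_pitch(rec.t, rec.gyro[:, 0], theta0)


def _check_lengths(*arrays) -> tuple:
    arrays = tuple(np.asarray(a, dtype=float) for a in arrays)
    if len({a.shape for a in arrays}) != 1:
        raise ParameterError(
            f"series length mismatch: {[a.shape for a in arrays]}"
        )
    return arrays


def vertical_accel_foot(acc_y, acc_z, theta3) -> np.ndarray:
    """Vertical acceleration of the foot: ``az*cos(theta) - ay*sin(theta)``."""
    acc_y, acc_z, theta3 = _check_lengths(acc_y, acc_z, theta3)
    return acc_z * np.cos(theta3) - acc_y * np.sin(theta3)


def vertical_accel_long_segment(acc_y, acc_z, theta) -> np.ndarray:
    """Vertical acceleration of a long segment: ``az*sin(theta) - ay*cos(theta)``."""
    acc_y, acc_z, theta = _check_lengths(acc_y, acc_z, theta)
    return acc_z * np.sin(theta) - acc_y * np.cos(theta)
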