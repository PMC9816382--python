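"""Transverse-plane segment kinematics.

Pelvic and upper-torso orientation are each defined by the virtual segment
connecting a bilateral marker pair (left/right ASIS, left/right acromion):
the left-minus-right vector is projected onto the horizontal (transverse)
plane and its heading taken with ``atan2``, then unwrapped over time so no
between-frame jump exceeds 180 deg.  Rotational velocity is the central
finite difference of that heading, in deg/s.  X-prime is the pelvic minus
upper-torso rotational velocity at each instant — negative during the
downswing, when the torso outpaces the pelvis.

Sign convention: the raw heading is counter-clockwise viewed from the up
direction.  A right-handed golfer's downswing is clockwise seen from above,
so for ``handedness="right"`` velocities are negated; this makes downswing
pelvis/torso velocities positive for either handedness.

No smoothing is applied by default.  An optional zero-lag 4th-order
Butterworth low-pass (``cutoff_hz``) is available for noisy captures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .marker_io import MarkerTrajectory, SwingRecording

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


class KinematicsError(ValueError):
    pass


@dataclass
class AngleSeries:
    """Unwrapped per-frame segment heading, degrees."""

    values: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        d = np.abs(np.diff(self.values))
        if d.size and np.nanmax(d) > 180.0 + 1e-9:
            raise KinematicsError("AngleSeries not unwrapped: a between-frame jump exceeds 180 deg")


@dataclass
class VelocitySeries:
    """Per-frame rotational velocity, deg/s."""

    values: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def horizontal_plane_indices(vertical_axis: str) -> tuple[int, int, float]:
    """Return (i, j, sign) such that heading = atan2(sign * v[j], v[i]).

    (i, j) are the horizontal axes in an order that makes the heading
    counter-clockwise about the *up* direction (right-hand rule).
    """
    axis, sgn = vertical_axis[0], vertical_axis[1]
    k = _AXIS_INDEX[axis]
    i, j = (k + 1) % 3, (k + 2) % 3
    return (i, j, 1.0) if sgn == "+" else (i, j, -1.0)


def segment_orientation(
    left: MarkerTrajectory,
    right: MarkerTrajectory,
    vertical_axis: str = "z+",
    sampling_rate: float = 1.0,
) -> AngleSeries:
    """Heading of the left-minus-right segment in the transverse plane.

    Frames where the projected segment is degenerate (horizontal norm
    < 1e-9 m, e.g. markers vertically stacked) inherit the previous frame's
    angle; an all-degenerate series is an error.  The result is unwrapped.
    """
    if left.n_frames != right.n_frames:
        raise KinematicsError("left/right trajectories differ in length")
    v = left.positions - right.positions
    i, j, s = horizontal_plane_indices(vertical_axis)
    x, y = v[:, i], s * v[:, j]
    norm = np.hypot(x, y)
    degenerate = norm < 1e-9
    if degenerate.all():
        raise KinematicsError("segment is degenerate (vertical) in every frame")
    raw = np.arctan2(y, x)
    # degenerate frames inherit the previous valid frame's angle
    if degenerate.any():
        raw = raw.copy()
        last = None
        for t in range(len(raw)):
            if degenerate[t]:
                if last is not None:
                    raw[t] = last
                else:  # leading degenerate frames inherit the first valid angle
                    raw[t] = raw[np.flatnonzero(~degenerate)[0]]
            else:
                last = raw[t]
    unwrapped = np.unwrap(raw)
    return AngleSeries(values=np.degrees(unwrapped), sampling_rate=sampling_rate)


def rotational_velocity(angles: AngleSeries) -> VelocitySeries:
    """Rate of change of a heading series, deg/s.

    Central differences in the interior (second-order accurate), one-sided
    differences at the two endpoints.
    """
    theta = angles.values
    if theta.size < 3:
        raise KinematicsError("rotational_velocity needs at least 3 frames")
    rate = angles.sampling_rate
    omega = np.empty_like(theta)
    omega[1:-1] = (theta[2:] - theta[:-2]) * rate / 2.0
    omega[0] = (theta[1] - theta[0]) * rate
    omega[-1] = (theta[-1] - theta[-2]) * rate
    return VelocitySeries(values=omega, sampling_rate=rate)


def xprime_velocity(pelvis: VelocitySeries, torso: VelocitySeries) -> VelocitySeries:
    """X-prime: pelvic minus upper-torso rotational velocity, per frame."""
    if pelvis.values.shape != torso.values.shape:
        raise KinematicsError("pelvis/torso velocity series differ in length")
    if pelvis.sampling_rate != torso.sampling_rate:
        raise KinematicsError("pelvis/torso velocity series differ in sampling rate")
    return VelocitySeries(values=pelvis.values - torso.values, sampling_rate=pelvis.sampling_rate)


def lowpass(values: np.ndarray, sampling_rate: float, cutoff_hz: float) -> np.ndarray:
    """Zero-lag 4th-order Butterworth low-pass (2nd order, forward-backward)."""
    b, a = butter(2, cutoff_hz / (sampling_rate / 2.0))
    return filtfilt(b, a, values)


@dataclass
class SwingKinematics:
    """Per-frame angles (deg) and velocities (deg/s) for one recording."""

    pelvis_angle: AngleSeries
    torso_angle: AngleSeries
    pelvis: VelocitySeries
    torso: VelocitySeries
    xprime: VelocitySeries


def swing_kinematics(rec: SwingRecording, cutoff_hz: float | None = None) -> SwingKinematics:
    """Compute pelvis, torso and X-prime kinematics for a recording.

    The handedness flag orients the velocity sign so that downswing pelvis
    and torso velocities come out positive regardless of which way the
    golfer actually rotates.
    """
    sign = -1.0 if rec.handedness == "right" else 1.0
    series = {}
    for name, (lrole, rrole) in (("pelvis", ("LASIS", "RASIS")), ("torso", ("LACR", "RACR"))):
        ang = segment_orientation(
            rec.marker(lrole), rec.marker(rrole), rec.vertical_axis, rec.sampling_rate
        )
        vals = sign * ang.values
        if cutoff_hz is not None:
            vals = lowpass(vals, rec.sampling_rate, cutoff_hz)
        series[name] = AngleSeries(values=vals, sampling_rate=rec.sampling_rate)
    pelvis_w = rotational_velocity(series["pelvis"])
    torso_w = rotational_velocity(series["torso"])
    return SwingKinematics(
        pelvis_angle=series["pelvis"],
        torso_angle=series["torso"],
        pelvis=pelvis_w,
        torso=torso_w,
        xprime=xprime_velocity(pelvis_w, torso_w),
    )
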