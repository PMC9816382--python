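"""Swing-phase event detection and clubhead speed at impact.

The swing cycle is segmented from the club and ball markers alone:

* backswing start — first frame whose vertical club-marker speed exceeds
  0.2 m/s, sustained for ``min_hold`` frames (the absolute value is used,
  since a takeaway may dip before rising);
* top of backswing — highest vertical club position between start and
  impact (ties resolved to the latest frame);
* impact — the frame immediately preceding the first rise in ball speed
  above ``ball_launch_threshold``;
* follow-through end — first local minimum of vertical club position after
  impact (falling back to the last frame, with a warning, if the height is
  still descending when the recording ends).

Clubhead speed at impact (CSI) corrects the distal-shaft marker speed for
the 5 cm offset between marker and clubface centre: a circle is fitted to
the marker path over the 50 frames either side of impact and the speed
scaled by (r + 0.05)/r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .kinematics import lowpass
from .marker_io import SwingRecording

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


class EventDetectionError(ValueError):
    pass


@dataclass
class SwingPhases:
    """Frame indices of the phase boundaries; strictly increasing."""

    backswing_start: int
    top: int
    impact: int
    followthrough_end: int

    def __post_init__(self) -> None:
        seq = (self.backswing_start, self.top, self.impact, self.followthrough_end)
        if not (seq[0] < seq[1] < seq[2] < seq[3]):
            raise EventDetectionError(f"phase indices not strictly ordered: {seq}")


@dataclass
class CircleFit:
    center: np.ndarray  # 3D, metres
    radius: float
    normal: np.ndarray  # unit vector
    rms_residual: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        if not self.radius > 0:
            raise ValueError("circle radius must be positive")


def vertical_position(rec: SwingRecording, role: str) -> np.ndarray:
    """Signed height of a marker along the up direction, metres."""
    axis, sgn = rec.vertical_axis[0], rec.vertical_axis[1]
    h = rec.marker(role).positions[:, _AXIS_INDEX[axis]]
    return h if sgn == "+" else -h


def _central_speed(values: np.ndarray, rate: float) -> np.ndarray:
    """Central-difference derivative, one-sided at the endpoints."""
    v = np.empty_like(values, dtype=float)
    v[1:-1] = (values[2:] - values[:-2]) * rate / 2.0
    v[0] = (values[1] - values[0]) * rate
    v[-1] = (values[-1] - values[-2]) * rate
    return v


def detect_backswing_start(
    rec: SwingRecording,
    threshold: float = 0.2,
    min_hold: int = 5,
    cutoff_hz: float | None = None,
) -> int:
    """First frame with |vertical club speed| > ``threshold`` m/s, sustained.

    The exceedance must hold for ``min_hold`` consecutive frames to reject
    single-frame noise spikes.  ``cutoff_hz`` optionally low-passes the
    club height before differentiation (for noisy captures).
    """
    h = vertical_position(rec, "CLUB")
    if np.isnan(h).any():
        raise EventDetectionError("CLUB trajectory has unfilled gaps")
    if cutoff_hz is not None:
        h = lowpass(h, rec.sampling_rate, cutoff_hz)
    speed = np.abs(_central_speed(h, rec.sampling_rate))
    above = speed > threshold
    n = len(above)
    run = 0
    for t in range(n):
        run = run + 1 if above[t] else 0
        if run >= max(min_hold, 1):
            return t - run + 1
    raise EventDetectionError(
        f"no swing detected: vertical club speed never exceeds {threshold} m/s "
        f"for {min_hold} consecutive frames"
    )


def detect_impact(
    rec: SwingRecording,
    backswing_start: int | None = None,
    ball_launch_threshold: float = 0.5,
    ball_static_tol: float = 0.05,
    cutoff_hz: float | None = None,
) -> int:
    """Frame immediately preceding the first rise in ball speed.

    The ball must be quasi-static over the pre-swing window: its drift —
    the displacement between the mean positions of the window's two halves,
    per unit time — must stay below ``ball_static_tol``.  Launch is the
    first frame after ``backswing_start`` whose frame-to-frame ball speed
    exceeds ``ball_launch_threshold``; impact is the frame before it.

    Ball speeds are never low-passed (a zero-phase filter would smear the
    launch step backwards in time); instead the launch threshold is raised
    to six noise SDs above the pre-swing mean speed when marker noise makes
    that higher, which keeps the detection exact on clean signals and
    false-trigger-free on noisy ones.  ``cutoff_hz`` only affects the
    backswing-start detection used to anchor the search.
    """
    if backswing_start is None:
        backswing_start = detect_backswing_start(rec, cutoff_hz=cutoff_hz)
    pos = rec.marker("BALL").positions
    if np.isnan(pos).any():
        raise EventDetectionError("BALL trajectory has unfilled gaps")
    rate = rec.sampling_rate
    # frame-to-frame speed; speed[t] is the speed over (t-1, t]
    step = np.linalg.norm(np.diff(pos, axis=0), axis=1) * rate
    speed = np.concatenate([[0.0], step])
    n_pre = max(backswing_start, 2)
    half = n_pre // 2
    if half >= 1:
        drift = np.linalg.norm(
            pos[half:n_pre].mean(axis=0) - pos[:half].mean(axis=0)
        ) * rate / max(n_pre - half, 1)
        if drift >= ball_static_tol:
            raise EventDetectionError(
                f"ball is already moving at the start of the recording "
                f"(drift {drift:.3f} m/s >= {ball_static_tol} m/s)"
            )
    pre = speed[1:n_pre]
    threshold = ball_launch_threshold
    if pre.size:
        threshold = max(threshold, float(pre.mean() + 6.0 * pre.std()))
    moving = np.flatnonzero(speed[backswing_start + 1 :] > threshold)
    if moving.size == 0:
        raise EventDetectionError("ball never moves: no impact found")
    t_star = backswing_start + 1 + int(moving[0])
    return t_star - 1


def detect_top(rec: SwingRecording, start: int, impact: int) -> int:
    """Frame of maximum vertical club position in [start, impact].

    Ties (a plateau of equal maxima) resolve to the latest such frame.
    """
    if not start < impact:
        raise EventDetectionError(f"start ({start}) must precede impact ({impact})")
    h = vertical_position(rec, "CLUB")[start : impact + 1]
    best = h.max()
    return start + int(np.flatnonzero(h == best)[-1])


def detect_followthrough_end(
    rec: SwingRecording, impact: int, cutoff_hz: float | None = None
) -> int:
    """First local minimum of vertical club position after impact.

    A plateau of equal minima counts from its first frame.  If the height is
    still descending at the end of the recording, the last frame is returned
    with a warning.
    """
    h = vertical_position(rec, "CLUB")
    if cutoff_hz is not None:
        h = lowpass(h, rec.sampling_rate, cutoff_hz)
    n = len(h)
    if impact >= n - 3:
        raise EventDetectionError("need at least 3 frames after impact")
    for t in range(impact + 1, n - 1):
        if h[t] <= h[t - 1] and h[t] <= h[t + 1]:
            if h[t] == h[t - 1] and t - 1 > impact:
                continue  # not the first frame of its plateau
            return t
    warnings.warn("no local height minimum after impact; using the last frame")
    return n - 1


def detect_phases(
    rec: SwingRecording,
    threshold: float = 0.2,
    min_hold: int = 5,
    ball_launch_threshold: float = 0.5,
    ball_static_tol: float = 0.05,
    cutoff_hz: float | None = None,
) -> SwingPhases:
    """Run all four detectors in order and return the phase boundaries."""
    start = detect_backswing_start(
        rec, threshold=threshold, min_hold=min_hold, cutoff_hz=cutoff_hz
    )
    impact = detect_impact(
        rec,
        backswing_start=start,
        ball_launch_threshold=ball_launch_threshold,
        ball_static_tol=ball_static_tol,
        cutoff_hz=cutoff_hz,
    )
    top = detect_top(rec, start, impact)
    end = detect_followthrough_end(rec, impact, cutoff_hz=cutoff_hz)
    return SwingPhases(backswing_start=start, top=top, impact=impact, followthrough_end=end)


# ---------------------------------------------------------------------------
# Circle fit and clubhead speed
# ---------------------------------------------------------------------------

def fit_circle_3d(points: np.ndarray) -> CircleFit:
    """Total-least-squares circle through a cloud of 3D points.

    The best-fit plane is the centroid plus the two largest-variance
    directions (SVD); points are projected into it and a planar circle
    fitted by the algebraic (Kasa) least-squares method.  Exact for
    noiseless circular arcs in any orientation.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] < 1e-12 * max(svals[0], 1.0):
        raise ValueError("points are collinear: no unique circle")
    e1, e2, normal = vt[0], vt[1], vt[2]
    u = centered @ e1
    v = centered @ e2
    # Kasa fit: minimise ||u^2+v^2 - 2au - 2bv - c||
    A = np.column_stack([2 * u, 2 * v, np.ones_like(u)])
    b = u**2 + v**2
    (a, bb, c), *_ = np.linalg.lstsq(A, b, rcond=None)
    radius = float(np.sqrt(c + a**2 + bb**2))
    center = centroid + a * e1 + bb * e2
    resid = np.sqrt(u**2 + v**2 - 2 * a * u - 2 * bb * v + a**2 + bb**2) - radius
    # out-of-plane deviation also counts toward the residual
    w = centered @ normal
    rms = float(np.sqrt(np.mean(resid**2 + w**2)))
    return CircleFit(center=center, radius=radius, normal=normal, rms_residual=rms)


def clubhead_speed_at_impact(
    rec: SwingRecording,
    phases: SwingPhases,
    window: int = 50,
    marker_offset: float = 0.05,
    min_window: int = 10,
) -> float:
    """Clubhead speed at impact (m/s), circle-radius corrected.

    Marker speed is the displacement of the distal-shaft marker from the
    impact frame to the next, times the sampling rate.  The correction
    scales by (r + marker_offset)/r with r from a circle fit over
    [impact - window, impact + window] (clipped to the recording; a warning
    is issued below 2*min_window + 1 frames).  A degenerate fit falls back
    to the raw marker speed with a warning.
    """
    pos = rec.marker("CLUB").positions
    t = phases.impact
    if t + 1 >= len(pos):
        raise EventDetectionError("impact is the final frame; no next sample for speed")
    v_m = float(np.linalg.norm(pos[t + 1] - pos[t]) * rec.sampling_rate)
    lo, hi = max(0, t - window), min(len(pos), t + window + 1)
    if hi - lo < 2 * min_window + 1:
        warnings.warn(
            f"only {hi - lo} frames available around impact for the circle fit "
            f"(wanted {2 * window + 1})"
        )
    try:
        fit = fit_circle_3d(pos[lo:hi])
    except ValueError:
        warnings.warn("degenerate circle fit around impact; using raw marker speed")
        return v_m
    return v_m * (fit.radius + marker_offset) / fit.radius
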