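import numpy as np
import pytest

from conftest import make_recording, static_positions

from golfspi import (
    SwingPhases,
    clubhead_speed_at_impact,
    detect_backswing_start,
    detect_followthrough_end,
    detect_impact,
    detect_phases,
    detect_top,
    fit_circle_3d,
)
from golfspi.swing_events import EventDetectionError


def _base_positions(n, club_z):
    """Static body markers, club with the given height profile, static ball."""
    club = np.column_stack([np.zeros(n), np.zeros(n), club_z])
    return {
        "LASIS": static_positions(n, [0.15, 0.0, 1.0]),
        "RASIS": static_positions(n, [-0.15, 0.0, 1.0]),
        "LACR": static_positions(n, [0.2, 0.0, 1.4]),
        "RACR": static_positions(n, [-0.2, 0.0, 1.4]),
        "CLUB": club,
        "BALL": static_positions(n, [0.0, 0.5, 0.05]),
    }


def test_backswing_start_on_constructed_step():
    rate, n = 240.0, 480
    z = np.zeros(n)
    rise_start = 240  # 1 s of stillness then 0.5 m/s rise
    z[rise_start:] = 0.5 * (np.arange(n - rise_start) / rate)
    rec = make_recording(_base_positions(n, z), rate=rate)
    found = detect_backswing_start(rec)
    assert abs(found - rise_start) <= 5


def test_backswing_threshold_is_strict():
    rate, n = 240.0, 480
    z = 0.19 * np.arange(n) / rate  # always just below 0.2 m/s
    rec = make_recording(_base_positions(n, z), rate=rate)
    with pytest.raises(EventDetectionError, match="no swing"):
        detect_backswing_start(rec)


def test_impact_is_frame_before_ball_launch():
    rate, n = 240.0, 600
    z = np.zeros(n)
    z[100:] = 0.5 * (np.arange(n - 100) / rate)  # club moves from frame 100
    pos = _base_positions(n, z)
    ball = static_positions(n, [0.0, 0.5, 0.05])
    launch = 400
    for t in range(launch + 1, n):
        ball[t] = ball[launch] + 30.0 * (t - launch) / rate * np.array([1.0, 0, 0])
    pos["BALL"] = ball
    rec = make_recording(pos, rate=rate)
    start = detect_backswing_start(rec)
    assert detect_impact(rec, backswing_start=start) == 400


def test_ball_drift_below_threshold_no_false_trigger():
    rate, n = 240.0, 600
    z = np.zeros(n)
    z[100:] = 0.5 * (np.arange(n - 100) / rate)
    pos = _base_positions(n, z)
    drift = 0.01 * np.arange(n)[:, None] / rate * np.array([1.0, 0, 0])
    pos["BALL"] = static_positions(n, [0.0, 0.5, 0.05]) + drift
    rec = make_recording(pos, rate=rate)
    with pytest.raises(EventDetectionError, match="never moves"):
        detect_impact(rec, backswing_start=100)


def test_ball_moving_at_start_is_an_error():
    rate, n = 240.0, 400
    z = np.zeros(n)
    z[50:] = 0.5 * (np.arange(n - 50) / rate)
    pos = _base_positions(n, z)
    roll = 0.2 * np.arange(n)[:, None] / rate * np.array([1.0, 0, 0])
    pos["BALL"] = static_positions(n, [0.0, 0.5, 0.05]) + roll
    rec = make_recording(pos, rate=rate)
    with pytest.raises(EventDetectionError, match="already moving"):
        detect_impact(rec, backswing_start=100)


def test_top_apex_and_plateau_tie_rule():
    n = 100
    z = np.concatenate([np.linspace(0, 1, 40), np.linspace(1, 0, 60)[1:], [0.0]])
    rec = make_recording(_base_positions(n, z))
    assert detect_top(rec, 0, 90) == 39
    z2 = np.concatenate([np.linspace(0, 1, 40), np.full(10, 1.0), np.linspace(1, 0, 51)[1:]])
    rec2 = make_recording(_base_positions(n, z2))
    assert detect_top(rec2, 0, 90) == 49  # latest frame of the plateau


def test_followthrough_end_vertex_and_fallback():
    n = 101
    imp = 30
    z = np.concatenate([np.zeros(imp + 1), np.linspace(0.0, -1.0, 30)[1:], np.linspace(-1.0, 0.5, 41)])
    rec = make_recording(_base_positions(n, z))
    assert detect_followthrough_end(rec, imp) == imp + 29  # V vertex
    z_mono = np.concatenate([np.zeros(imp + 1), np.linspace(0, -1, n - imp - 1)])
    rec2 = make_recording(_base_positions(n, z_mono))
    with pytest.warns(UserWarning, match="last frame"):
        assert detect_followthrough_end(rec2, imp) == n - 1


def test_phase_indices_strictly_ordered():
    with pytest.raises(EventDetectionError, match="ordered"):
        SwingPhases(backswing_start=10, top=5, impact=20, followthrough_end=30)


def _circle_points(radius, n=100, arc=2 * np.pi, rng=None, noise=0.0, rotate=True):
    t = np.linspace(0, arc, n)
    pts = np.column_stack([radius * np.cos(t), radius * np.sin(t), np.zeros(n)])
    if rotate:
        rng_r = np.random.default_rng(11)
        q, _ = np.linalg.qr(rng_r.normal(size=(3, 3)))
        pts = pts @ q.T + np.array([1.0, -2.0, 3.0])
    if noise and rng is not None:
        pts = pts + rng.normal(0, noise, size=pts.shape)
    return pts


def test_circle_fit_exact_on_noiseless_circle():
    fit = fit_circle_3d(_circle_points(1.4))
    assert fit.radius == pytest.approx(1.4, abs=1e-9)
    assert fit.rms_residual < 1e-9
    assert np.linalg.norm(fit.normal) == pytest.approx(1.0)


@pytest.mark.parametrize("arc_deg", [10, 45, 120, 350])
def test_circle_fit_exact_on_partial_arcs(arc_deg):
    fit = fit_circle_3d(_circle_points(0.7, arc=np.radians(arc_deg)))
    assert fit.radius == pytest.approx(0.7, rel=1e-7)


def test_circle_fit_noisy_radius_within_5mm():
    rng = np.random.default_rng(99)
    fit = fit_circle_3d(_circle_points(1.4, noise=0.001, rng=rng))
    assert fit.radius == pytest.approx(1.4, abs=0.005)


def test_circle_fit_three_points_is_circumcircle():
    # right triangle with legs 3-4: circumradius = hypotenuse / 2 = 2.5
    pts = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0], [0.0, 4.0, 0.0]])
    fit = fit_circle_3d(pts)
    assert fit.radius == pytest.approx(2.5, abs=1e-9)
    with pytest.raises(ValueError, match="collinear"):
        fit_circle_3d(np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]]))


def test_clubhead_speed_geometry():
    # marker on a circle r=1 m at angular rate w: corrected speed = 1.05 * w * r
    rate, w, r = 240.0, 10.0, 1.0
    n = 201
    t = np.arange(n) / rate
    club = np.column_stack([r * np.cos(w * t), r * np.sin(w * t), np.zeros(n)])
    pos = _base_positions(n, np.zeros(n))
    pos["CLUB"] = club
    rec = make_recording(pos, rate=rate)
    phases = SwingPhases(backswing_start=10, top=50, impact=100, followthrough_end=150)
    csi = clubhead_speed_at_impact(rec, phases)
    assert csi == pytest.approx(1.05 * w * r, rel=2e-3)


def test_clubhead_speed_straight_path_falls_back():
    rate, n = 240.0, 201
    club = np.column_stack([np.arange(n) / rate * 30.0, np.zeros(n), np.zeros(n)])
    pos = _base_positions(n, np.zeros(n))
    pos["CLUB"] = club
    rec = make_recording(pos, rate=rate)
    phases = SwingPhases(backswing_start=10, top=50, impact=100, followthrough_end=150)
    with pytest.warns(UserWarning, match="circle fit"):
        csi = clubhead_speed_at_impact(rec, phases)
    assert csi == pytest.approx(30.0, rel=1e-9)


def test_events_invariant_to_horizontal_translation(clean_swing):
    rec, truth = clean_swing
    shifted = make_recording(
        {role: rec.marker(role).positions + np.array([5.0, -3.0, 0.0])
         for role in rec.trajectories},
        rate=rec.sampling_rate,
    )
    assert detect_phases(shifted) == truth.phases
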