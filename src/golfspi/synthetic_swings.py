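"""Synthetic golf swings with known ground truth.

Marker-level recordings are built from closed-form angle profiles so every
pipeline stage can be tested without captured data:

* pelvis and torso transverse headings integrate piecewise raised-cosine
  velocity pulses that hit designed signed peaks — negative during the
  backswing, a designed downswing peak, a designed value at the impact
  frame and a designed follow-through peak;
* ASIS and acromion markers sit at half the segment width either side of
  fixed centres, perpendicular to each segment's heading (rigid segments);
* the distal club-shaft marker rides a tilted circle whose angle follows
  monotone cubic Hermite segments, giving a clean takeaway, a unique top,
  an impact at the arc's lowest point with a designed marker speed, and a
  first post-impact height minimum at the designed follow-through end;
* the ball is static at the impact point until the impact frame, then
  departs at constant velocity.

Ground-truth phase frames are what the event rules return on the noiseless
signals; designed metric truth comes from the analytic velocity profiles.
Optional Gaussian marker noise is seeded and reproducible.

Professional preset velocity targets are drawn around the published pro
cohort magnitudes (downswing pelvis 415.2 +/- 32.9 deg/s, torso 551.7 +/-
47.6, follow-through torso 929.2 +/- 185.1, ...).  The amateur preset is a
documented degradation — means scaled by 0.75, SDs doubled, pelvis peak
delayed — claiming separability, not amateur realism.

Also exposed here: the in-print worked-example fixture of 22 pro and 22
amateur principal-component triples with their published integer index
scores, used as the scoring stage's primary oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .marker_io import MarkerTrajectory, SwingRecording
from .spi_model import LabeledDataset
from .swing_events import SwingPhases, detect_phases
from .swing_metrics import METRIC_ORDER, MetricName, MetricVector, signed_peak
from .kinematics import VelocitySeries


class GeneratorError(ValueError):
    pass


@dataclass
class SwingParams:
    """Design parameters for one synthetic swing."""

    # designed rotational-velocity targets, deg/s
    pelvis_down: float = 415.2
    pelvis_impact: float = 288.8
    pelvis_post: float = 309.8
    torso_down: float = 551.7
    torso_impact: float = 458.5
    torso_post: float = 929.2
    # event times, seconds
    t_takeaway: float = 0.5
    t_top: float = 1.3
    t_impact: float = 1.6
    t_followthrough_end: float = 2.3
    duration: float = 2.6
    # peak timing as a fraction of its window
    pelvis_peak_frac: float = 0.55
    torso_peak_frac: float = 0.70
    post_peak_frac: float = 0.45
    back_frac: float = 0.4  # backswing peak magnitude / downswing peak
    # geometry
    pelvis_width: float = 0.30
    shoulder_width: float = 0.40
    club_radius: float = 1.4
    club_top_angle: float = 2.6  # rad
    club_ft_angle: float = 1.8  # rad, follow-through apex
    club_rest_angle: float = 1.2  # rad, where the club settles
    plane_tilt: float = 0.3  # rad, swing-plane tilt from vertical
    csi_target: float = 33.0  # m/s, clubhead speed at impact
    # acquisition
    sampling_rate: float = 240.0
    noise_sd: float = 0.0  # metres
    handedness: str = "right"
    seed: int = 0

    def __post_init__(self) -> None:
        times = (0.0, self.t_takeaway, self.t_top, self.t_impact,
                 self.t_followthrough_end, self.duration)
        if not all(a < b for a, b in zip(times, times[1:])):
            raise GeneratorError(f"event times not strictly ordered: {times}")
        if min(self.pelvis_width, self.shoulder_width, self.club_radius,
               self.sampling_rate, self.csi_target) <= 0:
            raise GeneratorError("widths, radius, rate and CSI must be positive")
        if self.noise_sd < 0:
            raise GeneratorError("noise SD must be non-negative")
        for seg in ("pelvis", "torso"):
            down, imp, post = (getattr(self, f"{seg}_{k}") for k in ("down", "impact", "post"))
            if not (down >= imp and post >= imp):
                raise GeneratorError(
                    f"{seg}: impact velocity must not exceed the downswing and "
                    f"follow-through peaks ({down=}, {imp=}, {post=})"
                )
        if not 0 < self.club_rest_angle < self.club_ft_angle:
            raise GeneratorError("need 0 < rest angle < follow-through apex angle")


@dataclass
class CohortTruth:
    """Designed ground truth for one generated swing."""

    swing_id: str
    subject_id: str
    group: str
    metrics: MetricVector
    phases: SwingPhases
    csi: float


# ---------------------------------------------------------------------------
# Closed-form building blocks
# ---------------------------------------------------------------------------

def _segment_velocity_profile(t: np.ndarray, p: SwingParams, seg: str) -> np.ndarray:
    """Piecewise raised-cosine rotational-velocity profile, deg/s."""
    down = getattr(p, f"{seg}_down")
    v_imp = getattr(p, f"{seg}_impact")
    post = getattr(p, f"{seg}_post")
    peak_frac = getattr(p, f"{seg}_peak_frac")
    t_pk = p.t_top + peak_frac * (p.t_impact - p.t_top)
    t_post_pk = p.t_impact + p.post_peak_frac * (p.t_followthrough_end - p.t_impact)
    w = np.zeros_like(t)

    def s(lo, hi):
        return np.clip((t - lo) / (hi - lo), 0.0, 1.0)

    m = (t >= p.t_takeaway) & (t < p.t_top)
    w[m] = -p.back_frac * down * 0.5 * (1 - np.cos(2 * np.pi * s(p.t_takeaway, p.t_top)[m]))
    m = (t >= p.t_top) & (t < t_pk)
    w[m] = down * 0.5 * (1 - np.cos(np.pi * s(p.t_top, t_pk)[m]))
    m = (t >= t_pk) & (t < p.t_impact)
    w[m] = v_imp + (down - v_imp) * 0.5 * (1 + np.cos(np.pi * s(t_pk, p.t_impact)[m]))
    m = (t >= p.t_impact) & (t < t_post_pk)
    w[m] = v_imp + (post - v_imp) * 0.5 * (1 - np.cos(np.pi * s(p.t_impact, t_post_pk)[m]))
    m = (t >= t_post_pk) & (t < p.t_followthrough_end)
    w[m] = post * 0.5 * (1 + np.cos(np.pi * s(t_post_pk, p.t_followthrough_end)[m]))
    return w


def _hermite(s: np.ndarray, p0: float, p1: float, m0: float, m1: float) -> np.ndarray:
    """Cubic Hermite on s in [0, 1] with endpoint values and velocities."""
    s2, s3 = s * s, s * s * s
    return (
        (2 * s3 - 3 * s2 + 1) * p0
        + (s3 - 2 * s2 + s) * m0
        + (-2 * s3 + 3 * s2) * p1
        + (s3 - s2) * m1
    )


def _club_angle_profile(t: np.ndarray, p: SwingParams) -> np.ndarray:
    """Swing-circle angle (rad): 0 at address/impact, positive at the top.

    Segment end velocities are chosen so each Hermite piece is monotone
    (no overshoot), giving one height maximum at the top and a first
    post-impact height minimum exactly at the designed follow-through end.
    """
    v_phi = p.csi_target / (p.club_radius + 0.05)  # marker angular rate at impact
    # follow-through apex time: linear-deceleration sweep of the apex angle
    t_apex = p.t_impact + 2 * p.club_ft_angle / v_phi
    if t_apex >= p.t_followthrough_end:
        raise GeneratorError("follow-through window too short for the designed CSI")
    phi = np.zeros_like(t)
    m = (t >= p.t_takeaway) & (t < p.t_top)
    s = (t[m] - p.t_takeaway) / (p.t_top - p.t_takeaway)
    phi[m] = _hermite(s, 0.0, p.club_top_angle, 0.0, 0.0)
    m = (t >= p.t_top) & (t < p.t_impact)
    dt = p.t_impact - p.t_top
    s = (t[m] - p.t_top) / dt
    phi[m] = _hermite(s, p.club_top_angle, 0.0, 0.0, -v_phi * dt)
    m = (t >= p.t_impact) & (t < t_apex)
    dt = t_apex - p.t_impact
    s = (t[m] - p.t_impact) / dt
    phi[m] = _hermite(s, 0.0, -p.club_ft_angle, -v_phi * dt, 0.0)
    m = (t >= t_apex) & (t < p.t_followthrough_end)
    s = (t[m] - t_apex) / (p.t_followthrough_end - t_apex)
    phi[m] = _hermite(s, -p.club_ft_angle, -p.club_rest_angle, 0.0, 0.0)
    phi[t >= p.t_followthrough_end] = -p.club_rest_angle
    return phi


def _pair_markers(center: np.ndarray, theta_deg: np.ndarray, width: float) -> tuple[np.ndarray, np.ndarray]:
    th = np.radians(theta_deg)
    u = np.column_stack([np.cos(th), np.sin(th), np.zeros_like(th)])
    left = center + 0.5 * width * u
    right = center - 0.5 * width * u
    return left, right


def generate_swing(params: SwingParams) -> tuple[SwingRecording, CohortTruth]:
    """Build one synthetic recording plus its ground-truth record."""
    p = params
    rate = p.sampling_rate
    n = int(round(p.duration * rate)) + 1
    t = np.arange(n) / rate

    # body segments: integrate designed velocity profiles
    sign = -1.0 if p.handedness == "right" else 1.0
    profiles = {}
    angles = {}
    for seg, theta0 in (("pelvis", 90.0), ("torso", 90.0)):
        w = _segment_velocity_profile(t, p, seg)
        theta_internal = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) / 2)]) / rate
        profiles[seg] = w
        angles[seg] = theta0 + sign * theta_internal

    pelvis_c = np.array([0.0, 0.0, 1.00])
    torso_c = np.array([0.0, 0.0, 1.42])
    lasis, rasis = _pair_markers(pelvis_c, angles["pelvis"], p.pelvis_width)
    lacr, racr = _pair_markers(torso_c, angles["torso"], p.shoulder_width)

    # club on a tilted circle; impact at the lowest point of the arc
    phi = _club_angle_profile(t, p)
    e1 = np.array([1.0, 0.0, 0.0])
    e2 = np.array([0.0, np.sin(p.plane_tilt), np.cos(p.plane_tilt)])  # "down" in-plane
    center = np.array([0.0, 0.5, p.club_radius * np.cos(p.plane_tilt) + 0.1])
    club = center + p.club_radius * (np.sin(phi)[:, None] * e1 - np.cos(phi)[:, None] * e2)

    # ball: static at the impact-frame club position, then constant velocity
    f_imp = int(round(p.t_impact * rate))
    ball = np.tile(club[f_imp], (n, 1))
    direction = np.array([1.0, 0.0, 0.15])
    direction /= np.linalg.norm(direction)
    speed = 1.4 * p.csi_target
    after = t > t[f_imp]
    ball[after] += (t[after] - t[f_imp])[:, None] * speed * direction

    def build(positions_map: dict[str, np.ndarray]) -> SwingRecording:
        trajectories = {
            role: MarkerTrajectory(label=role, positions=pos, missing=np.zeros(n, dtype=bool))
            for role, pos in positions_map.items()
        }
        return SwingRecording(
            trajectories=trajectories,
            sampling_rate=rate,
            handedness=p.handedness,
            vertical_axis="z+",
        )

    clean_map = {
        "LASIS": lasis, "RASIS": rasis, "LACR": lacr, "RACR": racr,
        "CLUB": club, "BALL": ball,
    }
    clean = build(clean_map)
    truth_phases = detect_phases(clean)  # event rules applied to the noiseless signals

    # designed metric truth from the analytic velocity profiles
    xprime = profiles["pelvis"] - profiles["torso"]
    series = {
        "pelvis": profiles["pelvis"], "torso": profiles["torso"], "xprime": xprime,
    }
    values: dict[MetricName, float] = {}
    ti, te, tt = truth_phases.impact, truth_phases.followthrough_end, truth_phases.top
    for name, w in series.items():
        vs = VelocitySeries(values=w, sampling_rate=rate)
        values[MetricName(f"{name}.peak_pre_impact")] = signed_peak(vs, (tt, ti))
        values[MetricName(f"{name}.at_impact")] = float(w[ti])
        values[MetricName(f"{name}.peak_post_impact")] = signed_peak(vs, (ti + 1, te))

    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        noisy_map = {
            role: pos + rng.normal(0.0, p.noise_sd, size=pos.shape)
            for role, pos in clean_map.items()
        }
        rec = build(noisy_map)
    else:
        rec = clean

    truth = CohortTruth(
        swing_id="", subject_id="", group="pro",
        metrics=MetricVector(swing_id="", subject_id="", group="pro", values=values),
        phases=truth_phases,
        csi=p.csi_target,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# Presets and cohorts
# ---------------------------------------------------------------------------

#: Pro velocity targets: (mean, SD) in deg/s, matching the published pro
#: cohort magnitudes; CSI in m/s.
PRO_TARGETS = {
    "pelvis_down": (415.2, 32.9),
    "pelvis_impact": (288.8, 70.9),
    "pelvis_post": (309.8, 42.1),
    "torso_down": (551.7, 47.6),
    "torso_impact": (458.5, 73.0),
    "torso_post": (929.2, 185.1),
    "csi_target": (33.15, 5.91),
}


@dataclass
class Preset:
    """A sampling distribution over SwingParams."""

    name: str
    targets: dict[str, tuple[float, float]]
    pelvis_peak_frac: float = 0.55
    noise_sd: float = 0.0

    def sample(self, rng: np.random.Generator, seed: int = 0) -> SwingParams:
        draw = {k: rng.normal(mu, sd) for k, (mu, sd) in self.targets.items()}
        # keep the designed profile well-posed: impact velocity below both peaks
        for seg in ("pelvis", "torso"):
            cap = 0.95 * min(draw[f"{seg}_down"], draw[f"{seg}_post"])
            draw[f"{seg}_impact"] = min(draw[f"{seg}_impact"], cap)
        draw["csi_target"] = max(draw["csi_target"], 15.0)
        return SwingParams(
            pelvis_peak_frac=self.pelvis_peak_frac,
            noise_sd=self.noise_sd,
            seed=seed,
            **draw,
        )


def pro_preset(noise_sd: float = 0.0) -> Preset:
    """Professional cohort: draws centred on the published pro magnitudes."""
    return Preset(name="pro", targets=dict(PRO_TARGETS), pelvis_peak_frac=0.55, noise_sd=noise_sd)


def amateur_preset(noise_sd: float = 0.0) -> Preset:
    """Amateur cohort: pro means scaled by 0.75, SDs doubled, pelvis peak
    delayed — an invented degradation claiming separability only."""
    targets = {k: (0.75 * mu, 2.0 * sd) for k, (mu, sd) in PRO_TARGETS.items()}
    return Preset(name="amateur", targets=targets, pelvis_peak_frac=0.80, noise_sd=noise_sd)


def generate_cohort(
    n_pro: int,
    n_amateur: int,
    seed: int,
    noise_sd: float = 0.0,
) -> tuple[list[SwingRecording], list[CohortTruth]]:
    """Generate a labelled cohort, one swing per subject, seed-deterministic."""
    if n_pro < 2 or n_amateur < 2:
        raise GeneratorError("need at least 2 subjects per group")
    rng = np.random.default_rng(seed)
    recordings: list[SwingRecording] = []
    truths: list[CohortTruth] = []
    for group, preset, count in (
        ("pro", pro_preset(noise_sd), n_pro),
        ("amateur", amateur_preset(noise_sd), n_amateur),
    ):
        for i in range(count):
            swing_seed = int(rng.integers(2**31 - 1))
            params = preset.sample(rng, seed=swing_seed)
            rec, truth = generate_swing(params)
            sid = f"{group}{i + 1:02d}"
            truth = replace(
                truth,
                swing_id=f"{sid}_s1",
                subject_id=sid,
                group=group,
                metrics=replace(truth.metrics, swing_id=f"{sid}_s1", subject_id=sid, group=group),
            )
            recordings.append(rec)
            truths.append(truth)
    return recordings, truths


# ---------------------------------------------------------------------------
# In-print worked-example fixture
# ---------------------------------------------------------------------------

# 22 professional swing trials: (subject, PC1, PC2, PC3, printed SPI)
_FIXTURE_PRO = [
    ("Pro 1", 2.16, -0.47, -0.49, 92), ("Pro 1", 2.36, -0.65, 0.16, 90),
    ("Pro 2", 0.22, -1.47, -0.80, 97), ("Pro 2", 0.23, -1.42, -0.54, 98),
    ("Pro 3", 0.98, 1.02, 0.25, 99), ("Pro 3", 1.27, 0.78, 1.12, 95),
    ("Pro 4", -1.22, -0.60, -0.68, 99), ("Pro 4", -1.24, -0.59, -1.12, 96),
    ("Pro 5", -1.09, -0.72, 0.44, 100), ("Pro 5", -0.64, -1.37, 1.11, 95),
    ("Pro 6", -0.16, 1.68, 0.13, 97), ("Pro 6", 0.10, 2.50, -0.30, 90),
    ("Pro 7", -0.52, -0.02, 2.00, 93), ("Pro 7", -0.52, -0.21, 2.09, 93),
    ("Pro 8", 0.82, -0.09, -1.58, 96), ("Pro 8", -0.64, 0.07, -0.74, 106),
    ("Pro 9", -0.56, 0.61, 1.02, 101), ("Pro 9", -0.18, -0.17, 0.17, 126),
    ("Pro 10", -0.96, 0.87, -0.92, 98), ("Pro 10", -0.72, 0.94, -1.38, 95),
    ("Pro 11", 0.21, -0.19, 0.05, 126), ("Pro 11", 0.09, -0.48, 0.00, 118),
]

# 22 amateur rows of the oversampled set; the first five are the original
# amateur swings (their printed scores match the participant table), the
# rest are synthetic oversamples.
_FIXTURE_AMATEUR = [
    (-2.61, -0.36, -2.48, 84), (-3.14, -1.66, -4.28, 77), (-1.20, -2.19, -3.84, 80),
    (-1.27, 2.13, 4.37, 78), (-1.10, 2.09, 1.65, 88), (-1.64, 1.23, 0.20, 93),
    (-2.18, 0.35, -1.29, 90), (-1.90, -2.00, -4.00, 79), (-2.49, -0.52, -2.60, 84),
    (-1.63, -1.63, -3.42, 82), (-2.20, -0.89, -2.88, 83), (-1.70, 1.13, 0.02, 94),
    (-2.72, -0.61, -2.83, 82), (-2.76, -0.71, -2.98, 82), (-1.13, 2.10, 2.01, 86),
    (-2.71, -0.59, -2.81, 82), (-1.28, -2.08, -3.76, 80), (-2.72, -0.62, -2.84, 82),
    (-1.54, -1.75, -3.51, 81), (-2.68, -0.51, -2.69, 83), (-1.91, -1.27, -3.16, 83),
    (-2.85, -0.95, -3.30, 80),
]

N_ORIGINAL_AMATEURS = 5


def worked_example_fixture() -> tuple[LabeledDataset, np.ndarray]:
    """The published per-swing PC triples and their printed integer scores.

    Returns a dataset of 22 pro + 22 amateur PC vectors (amateur rows
    beyond the first five flagged synthetic) and the 44 printed SPIs.
    """
    X, groups, subjects, swings, synthetic, printed = [], [], [], [], [], []
    for i, (subj, a, b, c, s) in enumerate(_FIXTURE_PRO):
        X.append((a, b, c))
        groups.append("pro")
        subjects.append(subj)
        swings.append(f"pro_{i}")
        synthetic.append(False)
        printed.append(s)
    for i, (a, b, c, s) in enumerate(_FIXTURE_AMATEUR):
        X.append((a, b, c))
        groups.append("amateur")
        subjects.append(f"Amateur {i + 1}" if i < N_ORIGINAL_AMATEURS else "synthetic")
        swings.append(f"amateur_{i}")
        synthetic.append(i >= N_ORIGINAL_AMATEURS)
        printed.append(s)
    ds = LabeledDataset(
        X=np.array(X, dtype=float),
        groups=np.array(groups),
        subject_ids=np.array(subjects),
        swing_ids=np.array(swings),
        synthetic=np.array(synthetic),
        metric_names=(),
    )
    return ds, np.array(printed, dtype=float)
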