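"""The nine candidate rotational metrics of a golf swing.

For each of three velocity signals — pelvis, upper torso and X-prime
(pelvis minus torso) — three scalars are extracted per swing:

* peak pre-impact: the signed extremum of largest magnitude over the
  downswing window [top of backswing, impact];
* at impact: the value at the impact frame;
* peak post-impact: the signed extremum over (impact, follow-through end].

Peaks keep their sign (X-prime peaks are negative); ties resolve to the
earliest frame.  The downswing window starts at the top of the backswing
so that backswing-direction extrema cannot masquerade as downswing peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .kinematics import SwingKinematics, VelocitySeries, swing_kinematics
from .marker_io import SwingRecording
from .swing_events import SwingPhases


class MetricName(str, Enum):
    """The nine candidate metrics, in canonical order."""

    PELVIS_PEAK_PRE_IMPACT = "pelvis.peak_pre_impact"
    PELVIS_AT_IMPACT = "pelvis.at_impact"
    PELVIS_PEAK_POST_IMPACT = "pelvis.peak_post_impact"
    TORSO_PEAK_PRE_IMPACT = "torso.peak_pre_impact"
    TORSO_AT_IMPACT = "torso.at_impact"
    TORSO_PEAK_POST_IMPACT = "torso.peak_post_impact"
    XPRIME_PEAK_PRE_IMPACT = "xprime.peak_pre_impact"
    XPRIME_AT_IMPACT = "xprime.at_impact"
    XPRIME_PEAK_POST_IMPACT = "xprime.peak_post_impact"


#: Canonical ordering used everywhere subsets are enumerated or printed.
METRIC_ORDER: tuple[MetricName, ...] = tuple(MetricName)


@dataclass
class MetricVector:
    """One swing's nine metric values (deg/s) plus identity and group."""

    swing_id: str
    subject_id: str
    group: str  # {"pro", "amateur"}
    values: dict[MetricName, float]

    def __post_init__(self) -> None:
        if self.group not in ("pro", "amateur"):
            raise ValueError(f"group must be 'pro' or 'amateur', got {self.group!r}")
        missing = [m for m in MetricName if m not in self.values]
        if missing:
            raise ValueError(f"metric vector missing {[m.value for m in missing]}")
        bad = [m.value for m, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite metric values: {bad}")

    def as_array(self, subset: Iterable[MetricName] | None = None) -> np.ndarray:
        names = list(subset) if subset is not None else list(METRIC_ORDER)
        return np.array([self.values[m] for m in names], dtype=float)


def signed_peak(series: VelocitySeries, window: tuple[int, int]) -> float:
    """Signed value of largest magnitude within [lo, hi] (inclusive).

    Ties in magnitude resolve to the earliest frame.
    """
    lo, hi = window
    if hi < lo:
        raise ValueError(f"empty window [{lo}, {hi}]")
    seg = series.values[lo : hi + 1]
    if seg.size == 0:
        raise ValueError(f"window [{lo}, {hi}] is outside the series")
    return float(seg[int(np.argmax(np.abs(seg)))])


def extract_metrics(
    rec: SwingRecording,
    phases: SwingPhases,
    swing_id: str = "",
    subject_id: str = "",
    group: str = "pro",
    cutoff_hz: float | None = None,
    kin: SwingKinematics | None = None,
) -> MetricVector:
    """Extract the nine metrics from one recording.

    The pre-impact window is [top, impact] (impact frame included); the
    post-impact window is (impact, follow-through end] (impact excluded).
    """
    if kin is None:
        kin = swing_kinematics(rec, cutoff_hz=cutoff_hz)
    signals = {"pelvis": kin.pelvis, "torso": kin.torso, "xprime": kin.xprime}
    t_top, t_imp, t_end = phases.top, phases.impact, phases.followthrough_end
    values: dict[MetricName, float] = {}
    for prefix, series in signals.items():
        values[MetricName(f"{prefix}.peak_pre_impact")] = signed_peak(series, (t_top, t_imp))
        values[MetricName(f"{prefix}.at_impact")] = float(series.values[t_imp])
        values[MetricName(f"{prefix}.peak_post_impact")] = signed_peak(series, (t_imp + 1, t_end))
    return MetricVector(swing_id=swing_id, subject_id=subject_id, group=group, values=values)


# ---------------------------------------------------------------------------
# Metrics interchange CSV (consumed by the SPI model stage)
# ---------------------------------------------------------------------------

def metrics_to_frame(vectors: Iterable[MetricVector]) -> pd.DataFrame:
    """Tabulate metric vectors: one row per swing, one column per metric."""
    rows = []
    for mv in vectors:
        row: dict[str, object] = {
            "swing_id": mv.swing_id,
            "subject_id": mv.subject_id,
            "group": mv.group,
        }
        row.update({m.value: mv.values[m] for m in METRIC_ORDER})
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_metrics(df: pd.DataFrame) -> list[MetricVector]:
    needed = {"swing_id", "subject_id", "group"} | {m.value for m in METRIC_ORDER}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"metrics table missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            MetricVector(
                swing_id=str(row["swing_id"]),
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                values={m: float(row[m.value]) for m in METRIC_ORDER},
            )
        )
    return out


def write_metrics_csv(vectors: Iterable[MetricVector], path: str | Path) -> None:
    metrics_to_frame(vectors).to_csv(path, index=False)


def read_metrics_csv(path: str | Path) -> list[MetricVector]:
    return frame_to_metrics(pd.read_csv(path))
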