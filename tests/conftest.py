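import numpy as np
import pytest

from golfspi import (
    LabeledDataset,
    MarkerTrajectory,
    SwingParams,
    SwingRecording,
    detect_phases,
    extract_metrics,
    generate_cohort,
    generate_swing,
)


@pytest.fixture(scope="session")
def clean_swing():
    """One noiseless default-parameter synthetic swing plus ground truth."""
    return generate_swing(SwingParams())


@pytest.fixture(scope="session")
def cohort():
    """The 11-pro / 5-amateur noiseless synthetic cohort, seed 1."""
    return generate_cohort(11, 5, seed=1)


@pytest.fixture(scope="session")
def cohort_dataset(cohort):
    """Metric vectors extracted from the synthetic cohort, as a dataset."""
    recs, truths = cohort
    vectors = []
    for rec, tr in zip(recs, truths):
        phases = detect_phases(rec)
        vectors.append(
            extract_metrics(rec, phases, swing_id=tr.swing_id,
                            subject_id=tr.subject_id, group=tr.group)
        )
    return LabeledDataset.from_metric_vectors(vectors)


def make_recording(positions: dict[str, np.ndarray], rate: float = 240.0,
                   handedness: str = "right", vertical_axis: str = "z+",
                   missing: dict[str, np.ndarray] | None = None) -> SwingRecording:
    """Assemble a recording from per-role position arrays (helper)."""
    n = next(iter(positions.values())).shape[0]
    trajectories = {}
    for role, pos in positions.items():
        mask = (missing or {}).get(role, np.zeros(n, dtype=bool))
        trajectories[role] = MarkerTrajectory(label=role, positions=pos, missing=mask)
    return SwingRecording(trajectories=trajectories, sampling_rate=rate,
                          handedness=handedness, vertical_axis=vertical_axis)


def static_positions(n: int, where: np.ndarray) -> np.ndarray:
    return np.tile(np.asarray(where, dtype=float), (n, 1))
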