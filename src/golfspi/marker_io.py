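"""Reading, validating and writing marker-trajectory recordings.

A golf-swing recording is a set of six labelled marker trajectories —
bilateral ASIS markers for the pelvis, bilateral acromion markers for the
upper torso, a marker on the distal club shaft and one on the ball —
sampled at a fixed rate by an optical motion-capture system.  Two plain-text
formats are supported:

* TRC (Motion Analysis / OpenSim dialect): tab-separated, 5-line header,
  read and write.
* A documented CSV dialect with ``#key=value`` metadata rows, read and
  write.  This is the package's canonical interchange format.

Internally everything is SI: positions in metres, rates in Hz.  TRC files
declaring ``Units mm`` are converted on read.  Missing samples (blank
cells) are carried as a per-frame boolean mask, never as silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

#: The six marker roles every recording must provide.
ROLES = ("LASIS", "RASIS", "LACR", "RACR", "CLUB", "BALL")

#: Default marker-label -> role mapping, matching common lab conventions.
DEFAULT_ROLE_MAP: dict[str, str] = {
    "L.ASIS": "LASIS",
    "R.ASIS": "RASIS",
    "L.Acromion": "LACR",
    "R.Acromion": "RACR",
    "L.ACR": "LACR",
    "R.ACR": "RACR",
    "LASIS": "LASIS",
    "RASIS": "RASIS",
    "LACR": "LACR",
    "RACR": "RACR",
    "Club": "CLUB",
    "CLUB": "CLUB",
    "Ball": "BALL",
    "BALL": "BALL",
}

VALID_VERTICAL = ("x+", "x-", "y+", "y-", "z+", "z-")


class MarkerIOError(ValueError):
    """Base class for recording parse/validation failures."""


class MissingRoleError(MarkerIOError):
    """A required marker role is absent from the file."""

    def __init__(self, missing: Sequence[str]):
        self.missing = tuple(missing)
        super().__init__(f"recording is missing required marker roles: {', '.join(self.missing)}")


class ParseError(MarkerIOError):
    """Malformed file content; carries a 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        where = f" (line {line})" if line is not None else ""
        super().__init__(f"{message}{where}")


@dataclass
class MarkerTrajectory:
    """One marker's 3D positions, metres, one row per frame.

    ``missing`` is True where the sample was absent in the source file;
    positions there are NaN and must not be used before gap filling.
    """

    label: str
    positions: np.ndarray  # (n_frames, 3) float64, metres
    missing: np.ndarray  # (n_frames,) bool

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise MarkerIOError(f"{self.label}: positions must be (n, 3)")
        if self.missing.shape != (self.positions.shape[0],):
            raise MarkerIOError(f"{self.label}: mask length != frame count")
        valid = self.positions[~self.missing]
        if valid.size and not np.all(np.isfinite(valid)):
            raise MarkerIOError(f"{self.label}: non-finite coordinates outside the missing mask")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]


@dataclass
class SwingRecording:
    """A validated six-marker recording with its acquisition metadata."""

    trajectories: dict[str, MarkerTrajectory]  # keyed by role
    sampling_rate: float  # Hz
    handedness: str = "right"  # {"right", "left"}
    vertical_axis: str = "z+"  # axis letter + up-direction sign

    def __post_init__(self) -> None:
        missing = [r for r in ROLES if r not in self.trajectories]
        if missing:
            raise MissingRoleError(missing)
        if not self.sampling_rate > 0:
            raise MarkerIOError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if self.handedness not in ("right", "left"):
            raise MarkerIOError(f"handedness must be 'right' or 'left', got {self.handedness!r}")
        if self.vertical_axis not in VALID_VERTICAL:
            raise MarkerIOError(
                f"vertical_axis must be one of {VALID_VERTICAL}, got {self.vertical_axis!r}"
            )
        lengths = {t.n_frames for t in self.trajectories.values()}
        if len(lengths) != 1:
            raise MarkerIOError(f"trajectories have unequal lengths: {sorted(lengths)}")

    @property
    def n_frames(self) -> int:
        return next(iter(self.trajectories.values())).n_frames

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.sampling_rate

    def marker(self, role: str) -> MarkerTrajectory:
        return self.trajectories[role]


# ---------------------------------------------------------------------------
# TRC
# ---------------------------------------------------------------------------

def read_trc(
    path: str | Path,
    role_map: Mapping[str, str] | None = None,
    handedness: str = "right",
    vertical_axis: str = "z+",
) -> SwingRecording:
    """Read a Motion Analysis / OpenSim TRC file.

    The 5-line header declares DataRate, NumFrames, Units and the marker
    labels; labels are mapped to roles through ``role_map`` (defaults to
    :data:`DEFAULT_ROLE_MAP`).  Positions in mm are converted to metres.
    Blank coordinate cells become masked frames.
    """
    role_map = dict(DEFAULT_ROLE_MAP if role_map is None else role_map)
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 6:
        raise ParseError(f"{path}: TRC file has fewer than 6 lines")

    keys = lines[1].rstrip("\n").split("\t")
    vals = lines[2].rstrip("\n").split("\t")
    header = dict(zip(keys, vals))
    try:
        rate = float(header["DataRate"])
        n_markers = int(header["NumMarkers"])
        units = header["Units"].strip().lower()
    except (KeyError, ValueError) as exc:
        raise ParseError(f"{path}: malformed TRC header: {exc}", line=3) from None
    if units not in ("m", "mm"):
        raise ParseError(f"{path}: unsupported Units token {units!r}", line=3)
    scale = 0.001 if units == "mm" else 1.0

    labels = [tok for tok in lines[3].rstrip("\n").split("\t")[2:] if tok.strip()]
    if len(labels) != n_markers:
        raise ParseError(
            f"{path}: header declares {n_markers} markers but {len(labels)} labels found", line=4
        )

    data_lines = [(i + 1, ln) for i, ln in enumerate(lines[5:], start=5) if ln.strip()]
    n_frames = len(data_lines)
    n_cols = 2 + 3 * n_markers
    pos = np.full((n_markers, n_frames, 3), np.nan)
    mask = np.zeros((n_markers, n_frames), dtype=bool)
    for row, (lineno, ln) in enumerate(data_lines):
        cells = ln.split("\t")
        if len(cells) < n_cols:
            cells = cells + [""] * (n_cols - len(cells))
        elif len(cells) > n_cols:
            raise ParseError(f"{path}: expected {n_cols} columns, got {len(cells)}", line=lineno + 1)
        for m in range(n_markers):
            triple = cells[2 + 3 * m : 5 + 3 * m]
            if any(c.strip() == "" for c in triple):
                mask[m, row] = True
                continue
            try:
                pos[m, row] = [float(c) for c in triple]
            except ValueError:
                raise ParseError(f"{path}: non-numeric coordinate", line=lineno + 1) from None
    pos *= scale

    trajectories: dict[str, MarkerTrajectory] = {}
    for m, label in enumerate(labels):
        role = role_map.get(label)
        if role is None or role in trajectories:
            continue
        trajectories[role] = MarkerTrajectory(label=label, positions=pos[m], missing=mask[m])
    absent = [r for r in ROLES if r not in trajectories]
    if absent:
        raise MissingRoleError(absent)
    return SwingRecording(
        trajectories=trajectories,
        sampling_rate=rate,
        handedness=handedness,
        vertical_axis=vertical_axis,
    )


def write_trc(rec: SwingRecording, path: str | Path, units: str = "mm") -> None:
    """Write a recording as a TRC file (positions converted to ``units``)."""
    if units not in ("m", "mm"):
        raise MarkerIOError(f"unsupported Units token {units!r}")
    scale = 1000.0 if units == "mm" else 1.0
    path = Path(path)
    n = rec.n_frames
    rate = rec.sampling_rate
    roles = list(ROLES)
    labels = [rec.trajectories[r].label for r in roles]
    lines = [
        f"PathFileType\t4\t(X/Y/Z)\t{path.name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\tOrigDataStartFrame\tOrigNumFrames",
        f"{rate:g}\t{rate:g}\t{n}\t{len(roles)}\t{units}\t{rate:g}\t1\t{n}",
        "Frame#\tTime\t" + "\t\t\t".join(labels),
        "\t\t" + "\t".join(f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(len(roles))),
    ]
    for f in range(n):
        cells = [str(f + 1), repr(f / rate)]
        for r in roles:
            traj = rec.trajectories[r]
            if traj.missing[f]:
                cells += ["", "", ""]
            else:
                cells += [repr(float(c) * scale) for c in traj.positions[f]]
        lines.append("\t".join(cells))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def read_csv_markers(path: str | Path) -> SwingRecording:
    """Read the package's CSV marker dialect.

    Metadata rows ``#rate=<Hz>``, ``#units=m|mm``, ``#vertical=<axis><sign>``
    and optional ``#handedness=right|left`` precede a header row
    ``frame,<role>_x,<role>_y,<role>_z,...``.  Empty cells mask the frame
    for that marker.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" in line:
                k, v = line[1:].split("=", 1)
                meta[k.strip()] = v.strip()
            continue
        if header is None:
            header = [c.strip() for c in raw.split(",")]
            continue
        rows.append((lineno, raw.split(",")))
    if header is None:
        raise ParseError(f"{path}: no header row found")
    if "rate" not in meta:
        raise ParseError(f"{path}: missing '#rate=' metadata row")
    rate = float(meta["rate"])
    units = meta.get("units", "m").lower()
    if units not in ("m", "mm"):
        raise ParseError(f"{path}: unknown units token {units!r}")
    scale = 0.001 if units == "mm" else 1.0
    vertical = meta.get("vertical", "z+")
    handedness = meta.get("handedness", "right")

    if header[0] != "frame":
        raise ParseError(f"{path}: first column must be 'frame', got {header[0]!r}")
    cols: dict[str, dict[str, int]] = {}
    for i, name in enumerate(header[1:], start=1):
        if "_" not in name:
            raise ParseError(f"{path}: malformed column name {name!r}")
        role, axis = name.rsplit("_", 1)
        if axis not in ("x", "y", "z"):
            raise ParseError(f"{path}: malformed column name {name!r}")
        slot = cols.setdefault(role, {})
        if axis in slot:
            raise ParseError(f"{path}: duplicate column for {role}_{axis}")
        slot[axis] = i
    for role, slot in cols.items():
        if set(slot) != {"x", "y", "z"}:
            raise ParseError(f"{path}: role {role!r} lacks a full x/y/z triple")

    n = len(rows)
    trajectories: dict[str, MarkerTrajectory] = {}
    arrays = {role: (np.full((n, 3), np.nan), np.zeros(n, dtype=bool)) for role in cols}
    for row_idx, (lineno, cells) in enumerate(rows):
        if len(cells) != len(header):
            raise ParseError(f"{path}: expected {len(header)} columns, got {len(cells)}", line=lineno)
        for role, slot in cols.items():
            pos, mask = arrays[role]
            triple = [cells[slot[a]] for a in ("x", "y", "z")]
            if any(c.strip() == "" for c in triple):
                mask[row_idx] = True
                continue
            try:
                pos[row_idx] = [float(c) for c in triple]
            except ValueError:
                raise ParseError(f"{path}: non-numeric coordinate", line=lineno) from None
    for role, (pos, mask) in arrays.items():
        trajectories[role] = MarkerTrajectory(label=role, positions=pos * scale, missing=mask)
    absent = [r for r in ROLES if r not in trajectories]
    if absent:
        raise MissingRoleError(absent)
    return SwingRecording(
        trajectories=trajectories,
        sampling_rate=rate,
        handedness=handedness,
        vertical_axis=vertical,
    )


def write_csv_markers(rec: SwingRecording, path: str | Path) -> None:
    """Write a recording in the CSV dialect (metres, full precision)."""
    path = Path(path)
    lines = [
        f"#rate={rec.sampling_rate:g}",
        "#units=m",
        f"#vertical={rec.vertical_axis}",
        f"#handedness={rec.handedness}",
        "frame," + ",".join(f"{r}_{a}" for r in ROLES for a in ("x", "y", "z")),
    ]
    for f in range(rec.n_frames):
        cells = [str(f)]
        for r in ROLES:
            traj = rec.trajectories[r]
            if traj.missing[f]:
                cells += ["", "", ""]
            else:
                cells += [repr(float(c)) for c in traj.positions[f]]
        lines.append(",".join(cells))
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Gap interpolation
# ---------------------------------------------------------------------------

def interpolate_gaps(rec: SwingRecording, max_gap: int) -> tuple[SwingRecording, dict[str, list[tuple[int, int]]]]:
    """Fill short marker dropouts by per-coordinate linear interpolation.

    Runs of at most ``max_gap`` consecutive missing frames that are bounded
    on both sides by valid samples are filled; longer interior runs and any
    leading/trailing run (which would need extrapolation) are left masked
    and reported.  Returns the repaired recording and a dict
    ``role -> [(start, stop), ...]`` of unfilled runs (stop exclusive).

    Idempotent: a second application is a no-op.
    """
    if max_gap < 0:
        raise MarkerIOError(f"max_gap must be >= 0, got {max_gap}")
    unfilled: dict[str, list[tuple[int, int]]] = {}
    new_traj: dict[str, MarkerTrajectory] = {}
    for role, traj in rec.trajectories.items():
        pos = traj.positions.copy()
        mask = traj.missing.copy()
        runs = _missing_runs(mask)
        kept: list[tuple[int, int]] = []
        for start, stop in runs:
            interior = start > 0 and stop < len(mask)
            if interior and (stop - start) <= max_gap:
                a, b = pos[start - 1], pos[stop]
                span = stop - (start - 1)
                for k in range(start, stop):
                    t = (k - (start - 1)) / span
                    pos[k] = a + t * (b - a)
                mask[start:stop] = False
            else:
                kept.append((start, stop))
        if kept:
            unfilled[role] = kept
        new_traj[role] = MarkerTrajectory(label=traj.label, positions=pos, missing=mask)
    return replace(rec, trajectories=new_traj), unfilled


def _missing_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    runs: list[tuple[int, int]] = []
    in_run = False
    start = 0
    for i, m in enumerate(mask):
        if m and not in_run:
            in_run, start = True, i
        elif not m and in_run:
            in_run = False
            runs.append((start, i))
    if in_run:
        runs.append((start, len(mask)))
    return runs
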