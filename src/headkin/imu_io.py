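"""Reading and writing the pipeline's on-disk formats.

The canonical interchange format for a single head-worn gyroscope recording is
a plain CSV with header ``t,gx,gy,gz``: time in seconds and the three angular
velocity components in deg/s, sampled at a fixed rate (128 Hz in the study
protocol).  A cohort is described by a manifest CSV
(``participant_id,group,task,file,fs_hz``) and, optionally, a subjective
difficulty-ratings CSV (``participant_id,task,rating``).

Groups are a closed enum — bilateral vestibulopathy (BV), unilateral
vestibulopathy (UV), healthy subjects (HS) — as are the eleven functional
mobility tasks and the four difficulty ratings.  Units are fixed: deg/s on
disk, no auto-detection.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    FormatError,
    IntegrityError,
    SensorRangeWarning,
)

__all__ = [
    "Group",
    "Task",
    "Rating",
    "SENSOR_RANGE_DPS",
    "GyroRecording",
    "ManifestRow",
    "CohortManifest",
    "DifficultyRating",
    "read_gyro_csv",
    "write_gyro_csv",
    "read_manifest",
    "write_manifest",
    "read_ratings",
    "write_ratings",
]

#: Nominal gyroscope full-scale range of the head sensor, deg/s.
SENSOR_RANGE_DPS = 2000.0


class Group(str, enum.Enum):
    """Participant group: bilateral / unilateral vestibulopathy or healthy."""

    BV = "BV"
    UV = "UV"
    HS = "HS"


class Task(str, enum.Enum):
    """The eleven functional mobility tasks of the protocol."""

    SORTING = "Sorting"
    HEAVY_LOAD = "Heavy load"
    STAIRS = "Stairs"
    UNEVEN_GROUND = "Uneven ground"
    TRAY = "Tray"
    WALK = "Walk"
    WOOD_BEAM = "Wood beam"
    INCLINED_PLANE = "Inclined plane"
    PICTURE_RECOGNITION = "Picture recognition"
    WALK_IN_THE_DARK = "Walk in the dark"
    UTURN = "UTurn"


class Rating(str, enum.Enum):
    """Subjective per-task difficulty rating."""

    EASY = "easy"
    MEDIUM = "medium"
    DIFFICULT = "difficult"
    UNABLE = "unable"


def _coerce_group(token: str) -> Group:
    try:
        return Group(token)
    except ValueError:
        raise FormatError(f"unknown group token: {token!r}") from None


def _coerce_task(token: str) -> Task:
    try:
        return Task(token)
    except ValueError:
        raise FormatError(f"unknown task token: {token!r}") from None


def _coerce_rating(token: str) -> Rating:
    try:
        return Rating(token)
    except ValueError:
        raise FormatError(f"unknown rating token: {token!r}") from None


@dataclass
class GyroRecording:
    """Raw 3-axis angular-velocity samples for one participant × task.

    Parameters
    ----------
    participant_id : str
        Cohort-unique participant identifier.
    group : Group
        Participant group (BV, UV or HS).
    task : Task
        Functional mobility task during which the recording was made.
    sampling_rate_hz : float
        Gyroscope sampling rate; 128 Hz in the study protocol.
    samples : ndarray of shape (T, 3)
        Angular velocity in deg/s, sensor-frame axes (x, y, z).
    """

    participant_id: str
    group: Group
    task: Task
    sampling_rate_hz: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.group = _coerce_group(self.group)
        self.task = _coerce_task(self.task)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise FormatError(
                f"samples must be a T x 3 matrix, got shape {self.samples.shape}"
            )
        if self.samples.shape[0] < 2:
            raise DegenerateInputError("a recording needs at least 2 samples")
        if not self.sampling_rate_hz > 0:
            raise FormatError("sampling_rate_hz must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise IntegrityError("recording contains non-finite samples")
        if np.any(np.abs(self.samples) > SENSOR_RANGE_DPS):
            warnings.warn(
                f"samples exceed the +/-{SENSOR_RANGE_DPS:g} deg/s sensor range",
                SensorRangeWarning,
                stacklevel=2,
            )

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass(frozen=True)
class ManifestRow:
    participant_id: str
    group: Group
    task: Task
    file_path: str
    sampling_rate_hz: float


@dataclass
class CohortManifest:
    """Validated list of cohort recordings.

    Invariants: (participant, task) pairs are unique and every participant
    belongs to exactly one group.
    """

    rows: list[ManifestRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, Task]] = set()
        groups: dict[str, Group] = {}
        for row in self.rows:
            key = (row.participant_id, row.task)
            if key in seen:
                raise IntegrityError(
                    f"duplicate manifest entry for {row.participant_id!r} / "
                    f"{row.task.value!r}"
                )
            seen.add(key)
            prev = groups.setdefault(row.participant_id, row.group)
            if prev is not row.group:
                raise IntegrityError(
                    f"participant {row.participant_id!r} listed in two groups"
                )

    @property
    def participants(self) -> list[str]:
        out: list[str] = []
        for row in self.rows:
            if row.participant_id not in out:
                out.append(row.participant_id)
        return out

    def __len__(self) -> int:
        return len(self.rows)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortManifest):
            return NotImplemented
        return sorted(self.rows, key=_row_key) == sorted(other.rows, key=_row_key)


def _row_key(row: ManifestRow) -> tuple[str, str]:
    return (row.participant_id, row.task.value)


@dataclass(frozen=True)
class DifficultyRating:
    """One participant's subjective difficulty rating for one task."""

    participant_id: str
    task: Task
    rating: Rating


GYRO_COLUMNS = ["t", "gx", "gy", "gz"]


def read_gyro_csv(
    path: str | Path,
    *,
    participant_id: str,
    group: Group | str,
    task: Task | str,
    sampling_rate_hz: float,
) -> GyroRecording:
    """Read one gyroscope CSV into a :class:`GyroRecording`.

    The ``t`` column is validated for strict monotonicity but otherwise
    ignored — the sampling rate comes from the metadata, keeping a single
    source of truth for timing.
    """
    frame = pd.read_csv(path)
    missing = [c for c in GYRO_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    t = frame["t"].to_numpy(dtype=float)
    if t.size >= 2 and np.any(np.diff(t) <= 0):
        raise IntegrityError(f"{path}: t column is not strictly increasing")
    samples = frame[["gx", "gy", "gz"]].to_numpy(dtype=float)
    return GyroRecording(
        participant_id=participant_id,
        group=group,
        task=task,
        sampling_rate_hz=sampling_rate_hz,
        samples=samples,
    )


def write_gyro_csv(rec: GyroRecording, path: str | Path) -> Path:
    """Write a recording as CSV ``t,gx,gy,gz`` with t = k / sampling rate."""
    path = Path(path)
    t = np.arange(rec.n_samples) / rec.sampling_rate_hz
    frame = pd.DataFrame(
        {"t": t, "gx": rec.samples[:, 0], "gy": rec.samples[:, 1], "gz": rec.samples[:, 2]}
    )
    frame.to_csv(path, index=False)
    return path


MANIFEST_COLUMNS = ["participant_id", "group", "task", "file", "fs_hz"]


def read_manifest(path: str | Path) -> CohortManifest:
    """Read and validate a cohort manifest CSV."""
    frame = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    rows = [
        ManifestRow(
            participant_id=str(r.participant_id),
            group=_coerce_group(r.group),
            task=_coerce_task(r.task),
            file_path=str(r.file),
            sampling_rate_hz=float(r.fs_hz),
        )
        for r in frame.itertuples()
    ]
    return CohortManifest(rows)


def write_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "group": r.group.value,
                "task": r.task.value,
                "file": r.file_path,
                "fs_hz": r.sampling_rate_hz,
            }
            for r in manifest.rows
        ],
        columns=MANIFEST_COLUMNS[:2] + ["task", "file", "fs_hz"],
    )
    frame.to_csv(path, index=False)
    return path


RATING_COLUMNS = ["participant_id", "task", "rating"]


def read_ratings(path: str | Path) -> list[DifficultyRating]:
    """Read difficulty ratings; at most one rating per (participant, task)."""
    frame = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in RATING_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    out: list[DifficultyRating] = []
    seen: set[tuple[str, Task]] = set()
    for r in frame.itertuples():
        task = _coerce_task(r.task)
        key = (str(r.participant_id), task)
        if key in seen:
            raise IntegrityError(
                f"{path}: duplicate rating for {r.participant_id!r} / {task.value!r}"
            )
        seen.add(key)
        out.append(
            DifficultyRating(
                participant_id=str(r.participant_id),
                task=task,
                rating=_coerce_rating(r.rating),
            )
        )
    return out


def write_ratings(ratings: list[DifficultyRating], path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(
        [
            {"participant_id": r.participant_id, "task": r.task.value, "rating": r.rating.value}
            for r in ratings
        ],
        columns=RATING_COLUMNS,
    )
    frame.to_csv(path, index=False)
    return path
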