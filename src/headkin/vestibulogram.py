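"""Vestibulogram construction: histogram modes, pooled quartiles, IQR area.

A *vestibulogram* plots, for one participant group, the per-task modes of the
angular-acceleration-norm distribution against those of the
angular-velocity-norm distribution, framed by the first and third quartiles
of the group's pooled distributions.  The mode (center of the most populated
histogram bin) summarizes each heavily skewed norm distribution by its most
characteristic value; the rectangle spanned by (Q1, Q3) on both axes
quantifies the group's overall movement range, and its area — reported in
units of 10^3 deg^2/s^3 — increases from bilateral vestibulopathy through
unilateral vestibulopathy to healthy subjects.

Histogram bins are half-open ``[origin + k*w, origin + (k+1)*w)``; ties
between equally populated bins break toward the lowest bin.  Quartiles are
empirical (linear-interpolation convention) on the raw pooled samples, so
they do not depend on the binning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ParameterError
from .imu_io import Group, Task
from .kinematics import KinematicSeries

__all__ = [
    "HistogramSpec",
    "TaskModeRecord",
    "VestibulogramSummary",
    "histogram_mode",
    "participant_task_modes",
    "group_task_mode",
    "pooled_quartiles",
    "iqr_area",
    "build_vestibulogram",
    "modes_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HistogramSpec:
    """Histogram binning for mode extraction.

    Defaults: 1 deg/s bins for velocity, 5 deg/s^2 bins for acceleration,
    both anchored at 0.
    """

    bin_width_velocity: float = 1.0
    bin_width_acceleration: float = 5.0
    origin: float = 0.0

    def __post_init__(self) -> None:
        if not (self.bin_width_velocity > 0 and self.bin_width_acceleration > 0):
            raise ParameterError("histogram bin widths must be positive")


@dataclass(frozen=True)
class TaskModeRecord:
    """Histogram modes for one participant on one task."""

    participant_id: str
    group: Group
    task: Task
    mode_velocity: float  # deg/s
    mode_acceleration: float  # deg/s^2


@dataclass
class VestibulogramSummary:
    """Group-level vestibulogram: per-task pooled modes, quartiles, IQR area."""

    group: Group
    task_modes: dict[Task, tuple[float, float]]  # task -> (mode_v, mode_a)
    q1_velocity: float
    q3_velocity: float
    q1_acceleration: float
    q3_acceleration: float
    iqr_area: float = field(init=False)  # 10^3 deg^2/s^3

    def __post_init__(self) -> None:
        self.iqr_area = iqr_area(
            (self.q1_velocity, self.q3_velocity, self.q1_acceleration, self.q3_acceleration)
        )

    def to_dict(self) -> dict:
        return {
            "group": self.group.value,
            "task_modes": {
                t.value: [mv, ma] for t, (mv, ma) in self.task_modes.items()
            },
            "q1_velocity": self.q1_velocity,
            "q3_velocity": self.q3_velocity,
            "q1_acceleration": self.q1_acceleration,
            "q3_acceleration": self.q3_acceleration,
            "iqr_area": self.iqr_area,
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path


def histogram_mode(values: np.ndarray, bin_width: float, origin: float = 0.0) -> float:
    """Center of the most populated half-open bin; ties -> lowest bin."""
    if bin_width <= 0:
        raise ParameterError("bin_width must be positive")
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise DegenerateInputError("cannot take the mode of an empty sample")
    if not np.all(np.isfinite(values)):
        raise DegenerateInputError("mode is undefined for non-finite values")
    idx = np.floor((values - origin) / bin_width).astype(np.int64)
    lo = idx.min()
    counts = np.bincount(idx - lo)
    k = int(np.argmax(counts)) + lo  # argmax returns the first (lowest) max
    return origin + (k + 0.5) * bin_width


def participant_task_modes(
    cohort: Iterable[KinematicSeries], spec: HistogramSpec | None = None
) -> list[TaskModeRecord]:
    """One :class:`TaskModeRecord` per processed (participant, task) series."""
    if spec is None:
        spec = HistogramSpec()
    out: list[TaskModeRecord] = []
    for series in cohort:
        if series is None or series.velocity_norm.size == 0:
            logger.warning("skipping empty series (participant unable to perform?)")
            continue
        out.append(
            TaskModeRecord(
                participant_id=series.participant_id,
                group=series.group,
                task=series.task,
                mode_velocity=histogram_mode(
                    series.velocity_norm, spec.bin_width_velocity, spec.origin
                ),
                mode_acceleration=histogram_mode(
                    series.acceleration_norm, spec.bin_width_acceleration, spec.origin
                ),
            )
        )
    return out


def group_task_mode(
    cohort: Iterable[KinematicSeries],
    group: Group,
    task: Task,
    spec: HistogramSpec | None = None,
) -> tuple[float, float]:
    """Modes of the sample pooled over all the group's participants on a task.

    The pooled mode is the mode of the concatenated norm samples, not the
    mode of per-participant modes.
    """
    if spec is None:
        spec = HistogramSpec()
    series = [s for s in cohort if s.group is group and s.task is task]
    if not series:
        raise DegenerateInputError(f"no data for group {group.value} task {task.value}")
    vel = [s.velocity_norm for s in series]
    acc = [s.acceleration_norm for s in series]
    mode_v = histogram_mode(np.concatenate(vel), spec.bin_width_velocity, spec.origin)
    mode_a = histogram_mode(np.concatenate(acc), spec.bin_width_acceleration, spec.origin)
    return mode_v, mode_a


def pooled_quartiles(
    cohort: Iterable[KinematicSeries], group: Group
) -> tuple[float, float, float, float]:
    """(Q1_v, Q3_v, Q1_a, Q3_a) of the group's pooled norm samples.

    Pooled over all tasks and participants; empirical percentiles with the
    linear-interpolation convention.
    """
    series = [s for s in cohort if s.group is group]
    if not series:
        raise DegenerateInputError(f"no data pooled for group {group.value}")
    vel = np.concatenate([s.velocity_norm for s in series])
    acc = np.concatenate([s.acceleration_norm for s in series])
    q1_v, q3_v = np.quantile(vel, [0.25, 0.75])
    q1_a, q3_a = np.quantile(acc, [0.25, 0.75])
    return float(q1_v), float(q3_v), float(q1_a), float(q3_a)


def iqr_area(quartiles: tuple[float, float, float, float]) -> float:
    """Q1–Q3 rectangle area, (Q3_v - Q1_v) * (Q3_a - Q1_a) / 1000.

    Unit 10^3 deg^2/s^3, the scale on which the group areas are reported.
    """
    q1_v, q3_v, q1_a, q3_a = quartiles
    if q1_v > q3_v or q1_a > q3_a:
        raise ParameterError("quartiles are inverted (q1 > q3)")
    return (q3_v - q1_v) * (q3_a - q1_a) / 1000.0


def build_vestibulogram(
    cohort: Iterable[KinematicSeries],
    group: Group,
    spec: HistogramSpec | None = None,
) -> VestibulogramSummary:
    """Assemble the full per-group summary (task modes, quartiles, area)."""
    if spec is None:
        spec = HistogramSpec()
    series = [s for s in cohort if s.group is group]
    if not series:
        raise DegenerateInputError(f"no processed data for group {group.value}")
    tasks = sorted({s.task for s in series}, key=lambda t: t.value)
    task_modes = {t: group_task_mode(series, group, t, spec) for t in tasks}
    q1_v, q3_v, q1_a, q3_a = pooled_quartiles(series, group)
    return VestibulogramSummary(
        group=group,
        task_modes=task_modes,
        q1_velocity=q1_v,
        q3_velocity=q3_v,
        q1_acceleration=q1_a,
        q3_acceleration=q3_a,
    )


def modes_to_frame(records: Iterable[TaskModeRecord]) -> pd.DataFrame:
    """Long-format table of per-participant task modes."""
    return pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "group": r.group.value,
                "task": r.task.value,
                "mode_velocity": r.mode_velocity,
                "mode_acceleration": r.mode_acceleration,
            }
            for r in records
        ]
    )
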