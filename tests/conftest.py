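import numpy as np
import pytest

from headkin import (
    CohortConfig,
    Group,
    GyroRecording,
    Task,
    generate_cohort,
    participant_task_modes,
    process_recording,
)
from headkin.synthetic import TaskProfile

SMALL_TASKS = {
    Task.WALK: 8.3,
    Task.SORTING: 9.0,
    Task.STAIRS: 14.0,
    Task.UTURN: 33.0,
}


def small_config(seed: int = 7, n_per_group: int = 3, duration_s: float = 10.0):
    return CohortConfig(
        group_sizes={Group.BV: n_per_group, Group.UV: n_per_group, Group.HS: n_per_group},
        task_profiles={
            t: TaskProfile(t, m, duration_s=duration_s) for t, m in SMALL_TASKS.items()
        },
        missing_probability={},
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 9-participant, 4-task synthetic cohort shared across tests."""
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def small_series(small_cohort):
    return [process_recording(r) for r in small_cohort.recordings.values()]


@pytest.fixture(scope="session")
def small_records(small_series):
    return participant_task_modes(small_series)


@pytest.fixture()
def constant_recording():
    """Pure constant rotation about x at 10 deg/s, 10 s at 128 Hz."""
    samples = np.tile([10.0, 0.0, 0.0], (1280, 1))
    return GyroRecording("p1", Group.HS, Task.WALK, 128.0, samples)
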