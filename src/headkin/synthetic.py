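"""Synthetic gyroscope cohorts with known ground truth.

Head rotation during functional mobility is band-limited — roughly 0.5-5 Hz —
so each recording is synthesized as a sum of random-phase sinusoids with
frequencies drawn uniformly in that band on each of the three axes, plus
high-frequency sensor noise above the 6 Hz analysis cutoff.  The pipeline is
linear and the vector norm absolutely homogeneous, so scaling the signal
scales the velocity-norm distribution (and its mode) exactly; each recording
is therefore calibrated by one multiplicative constant so that the mode of
its processed velocity norm equals a prescribed target.  The per-recording
calibration constant is found against the recording's own processed unit
realization, with a kernel-density argmax as the continuous mode estimate.

A cohort mimics the study design: three groups (19 BV / 20 UV / 20 HS),
eleven tasks, group scale factors ordering overall dispersion BV < UV < HS,
a participant-level random effect and cell-level noise on the target modes.
The generator emits the on-disk formats of :mod:`headkin.imu_io` plus a
ground-truth table of every cell's true modes, so downstream recovery is
testable without any external data.

Everything derives from one master seed; per-recording streams are split off
with a stable CRC-based hash of (participant, task), so regeneration is
byte-identical and order-independent.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal, stats

from .errors import ParameterError
from .imu_io import (
    CohortManifest,
    DifficultyRating,
    Group,
    GyroRecording,
    ManifestRow,
    Rating,
    Task,
    write_gyro_csv,
    write_manifest,
)
from .kinematics import ProcessingParams, process_recording
from .vestibulogram import HistogramSpec, histogram_mode

__all__ = [
    "TaskProfile",
    "CohortConfig",
    "SyntheticCohort",
    "DEFAULT_TASK_TARGETS",
    "generate_recording",
    "oracle_mode",
    "generate_cohort",
    "generate_ratings",
    "implied_cell_means",
    "implied_fixed_effects",
]

#: Baseline (scale = 1, i.e. BV-level) velocity-norm mode targets, deg/s.
#: With the default HS scale factor of 1.8 these place Walk near 15 deg/s,
#: Stairs near 25 deg/s and UTurn near 60 deg/s for healthy subjects, and a
#: generic ~8-13 deg/s band for the BV group, matching the reported ranges.
DEFAULT_TASK_TARGETS: dict[Task, float] = {
    Task.SORTING: 9.0,
    Task.HEAVY_LOAD: 13.0,
    Task.STAIRS: 14.0,
    Task.UNEVEN_GROUND: 9.5,
    Task.TRAY: 8.5,
    Task.WALK: 8.3,
    Task.WOOD_BEAM: 8.0,
    Task.INCLINED_PLANE: 9.0,
    Task.PICTURE_RECOGNITION: 9.5,
    Task.WALK_IN_THE_DARK: 9.0,
    Task.UTURN: 33.0,
}


@dataclass(frozen=True)
class TaskProfile:
    """Generation parameters for one task."""

    task: Task
    target_mode_velocity: float  # deg/s, at scale = 1
    oscillation_band: tuple[float, float] = (0.5, 5.0)  # Hz
    duration_s: float = 30.0
    noise_sd_highfreq: float = 1.0  # deg/s, injected above the analysis cutoff
    n_sinusoids: int = 6

    def __post_init__(self) -> None:
        if self.target_mode_velocity < 0:
            raise ParameterError("target mode must be non-negative")
        if not 0 < self.oscillation_band[0] < self.oscillation_band[1]:
            raise ParameterError("oscillation band must satisfy 0 < f_lo < f_hi")


def default_profiles(duration_s: float = 30.0) -> dict[Task, TaskProfile]:
    return {
        t: TaskProfile(task=t, target_mode_velocity=m, duration_s=duration_s)
        for t, m in DEFAULT_TASK_TARGETS.items()
    }


@dataclass
class CohortConfig:
    """Full specification of a synthetic cohort.

    Defaults reproduce the study's shape: 19/20/20 participants, 11 tasks,
    group scale factors 1.0 (BV) < 1.2 (UV) < 1.8 (HS).  The participant
    random effect and cell noise act additively on the target modes (deg/s).
    ``missing_probability`` removes (participant, task) cells, mirroring
    participants unable to perform a task; by default 17% of BV participants
    miss the Wood beam task.
    """

    group_sizes: dict[Group, int] = field(
        default_factory=lambda: {Group.BV: 19, Group.UV: 20, Group.HS: 20}
    )
    group_scales: dict[Group, float] = field(
        default_factory=lambda: {Group.BV: 1.0, Group.UV: 1.2, Group.HS: 1.8}
    )
    task_profiles: dict[Task, TaskProfile] = field(default_factory=default_profiles)
    participant_sd: float = 1.5  # deg/s, random intercept on the mode scale
    residual_sd: float = 1.0  # deg/s, cell-level noise on the mode scale
    missing_probability: dict[tuple[Group, Task], float] = field(
        default_factory=lambda: {(Group.BV, Task.WOOD_BEAM): 0.17}
    )
    fs_hz: float = 128.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.group_sizes.values()):
            raise ParameterError("group sizes must be >= 1")
        if any(s <= 0 for s in self.group_scales.values()):
            raise ParameterError("group scale factors must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "group_sizes" in raw:
            kwargs["group_sizes"] = {Group(k): int(v) for k, v in raw["group_sizes"].items()}
        if "group_scales" in raw:
            kwargs["group_scales"] = {Group(k): float(v) for k, v in raw["group_scales"].items()}
        if "task_targets" in raw:
            dur = float(raw.get("duration_s", 30.0))
            kwargs["task_profiles"] = {
                Task(k): TaskProfile(Task(k), float(v), duration_s=dur)
                for k, v in raw["task_targets"].items()
            }
        elif "duration_s" in raw:
            kwargs["task_profiles"] = default_profiles(float(raw["duration_s"]))
        for key in ("participant_sd", "residual_sd", "fs_hz"):
            if key in raw:
                kwargs[key] = float(raw[key])
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        return cls(**kwargs)


def _recording_seed(master_seed: int, participant_id: str, task: Task) -> np.random.SeedSequence:
    """Stable per-recording stream: CRC of (participant, task) + master seed."""
    tag = zlib.crc32(f"{participant_id}|{task.value}".encode())
    return np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, tag])


def _unit_signal(
    profile: TaskProfile, fs_hz: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-scale band-limited 3-axis oscillation, before calibration."""
    n = int(round(profile.duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    f_lo, f_hi = profile.oscillation_band
    out = np.zeros((n, 3))
    for axis in range(3):
        freqs = rng.uniform(f_lo, f_hi, size=profile.n_sinusoids)
        phases = rng.uniform(0, 2 * np.pi, size=profile.n_sinusoids)
        out[:, axis] = np.sin(
            2 * np.pi * freqs[None, :] * t[:, None] + phases[None, :]
        ).sum(axis=1)
    return out


def _highfreq_noise(
    n: int, fs_hz: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise high-passed above the analysis band (>= 10 Hz)."""
    if sd <= 0:
        return np.zeros((n, 3))
    white = rng.standard_normal((n, 3))
    sos = signal.butter(4, 10.0, btype="high", fs=fs_hz, output="sos")
    shaped = signal.sosfiltfilt(sos, white, axis=0)
    scale = shaped.std(axis=0)
    scale[scale == 0] = 1.0
    return shaped / scale * sd


def _kde_mode(values: np.ndarray, n_grid: int = 512) -> float:
    """Continuous mode estimate: argmax of a Gaussian KDE on a grid."""
    lo, hi = values.min(), values.max()
    if hi <= lo:
        return float(lo)
    grid = np.linspace(lo, hi, n_grid)
    dens = stats.gaussian_kde(values)(grid)
    return float(grid[np.argmax(dens)])


def _calibrate_amplitude(
    vel_norm_unit: np.ndarray, desired: float, bin_width: float, origin: float
) -> float:
    """One-dimensional search for the scale putting the binned mode on target.

    The chain is homogeneous, so scaling the signal scales every norm sample;
    the binned mode is a step function of the scale, searched by fixed-point
    iteration ``a <- a * desired / mode(a * x)``, keeping the best iterate.
    """
    a = desired / _kde_mode(vel_norm_unit)
    best_a, best_err = a, np.inf
    for _ in range(12):
        m = histogram_mode(a * vel_norm_unit, bin_width, origin)
        err = abs(m - desired)
        if err < best_err:
            best_a, best_err = a, err
        if err <= 0.5 * bin_width:
            break
        a *= desired / m
    return best_a


def _generate_calibrated(
    profile: TaskProfile,
    desired: float,
    fs_hz: float,
    rng: np.random.Generator,
    participant_id: str,
    group: Group,
    params: ProcessingParams,
    spec: HistogramSpec,
) -> tuple[np.ndarray, float, float]:
    """Calibrated noiseless samples plus the achieved (binned) true modes."""
    n = int(round(profile.duration_s * fs_hz))
    unit = _unit_signal(profile, fs_hz, rng)
    probe = GyroRecording(participant_id, group, profile.task, fs_hz, unit)
    processed = process_recording(probe, params)
    a = _calibrate_amplitude(
        processed.velocity_norm, desired, spec.bin_width_velocity, spec.origin
    )
    mode_v = histogram_mode(
        a * processed.velocity_norm, spec.bin_width_velocity, spec.origin
    )
    mode_a = histogram_mode(
        a * processed.acceleration_norm, spec.bin_width_acceleration, spec.origin
    )
    return a * unit, mode_v, mode_a


def generate_recording(
    profile: TaskProfile,
    participant_scale: float,
    fs_hz: float = 128.0,
    seed: int | np.random.SeedSequence = 0,
    *,
    participant_id: str = "sim",
    group: Group = Group.HS,
    params: ProcessingParams | None = None,
    spec: HistogramSpec | None = None,
) -> GyroRecording:
    """Synthesize one recording whose processed velocity-norm mode equals
    ``participant_scale * profile.target_mode_velocity``.

    The unit realization is pushed through the analysis chain once, then
    rescaled by a searched constant so that the default-binned mode of the
    processed velocity norm lands on the target (within one bin).  Sensor
    noise is injected above the analysis band afterwards.  A zero target
    yields an all-zero recording.
    """
    if profile.oscillation_band[1] >= fs_hz / 2:
        raise ParameterError("oscillation band extends to or beyond Nyquist")
    n = int(round(profile.duration_s * fs_hz))
    if n < 256:
        raise ParameterError("recording must contain at least 256 samples")
    if params is None:
        params = ProcessingParams()
    if spec is None:
        spec = HistogramSpec()
    rng = np.random.default_rng(seed)
    desired = participant_scale * profile.target_mode_velocity
    if desired <= 0:
        samples = np.zeros((n, 3))
    else:
        scaled, _, _ = _generate_calibrated(
            profile, desired, fs_hz, rng, participant_id, group, params, spec
        )
        samples = scaled + _highfreq_noise(n, fs_hz, profile.noise_sd_highfreq, rng)
    return GyroRecording(
        participant_id=participant_id,
        group=group,
        task=profile.task,
        sampling_rate_hz=fs_hz,
        samples=samples,
    )


def oracle_mode(
    profile: TaskProfile,
    participant_scale: float,
    n_samples: int = 100_000,
    fs_hz: float = 128.0,
    seed: int = 0,
    spec: HistogramSpec | None = None,
) -> tuple[float, float]:
    """Brute-force ground truth: empirical modes of a long processed realization."""
    if n_samples < 100_000:
        raise ParameterError("oracle needs at least 1e5 samples")
    if spec is None:
        spec = HistogramSpec()
    long_profile = replace(profile, duration_s=n_samples / fs_hz)
    rec = generate_recording(long_profile, participant_scale, fs_hz, seed)
    processed = process_recording(rec)
    mode_v = histogram_mode(processed.velocity_norm, spec.bin_width_velocity, spec.origin)
    mode_a = histogram_mode(
        processed.acceleration_norm, spec.bin_width_acceleration, spec.origin
    )
    return mode_v, mode_a


@dataclass
class SyntheticCohort:
    """In-memory cohort: manifest, recordings and ground-truth cell table."""

    config: CohortConfig
    manifest: CohortManifest
    recordings: dict[tuple[str, Task], GyroRecording]
    ground_truth: pd.DataFrame  # participant_id, group, task, true modes

    def write(self, out_dir: str | Path) -> Path:
        """Write recordings, manifest and ground_truth.csv to a directory."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for (pid, task), rec in self.recordings.items():
            fname = f"{pid}_{task.value.replace(' ', '_')}.csv"
            write_gyro_csv(rec, out_dir / fname)
            rows.append(
                ManifestRow(pid, rec.group, task, fname, rec.sampling_rate_hz)
            )
        write_manifest(CohortManifest(rows), out_dir / "manifest.csv")
        self.ground_truth.to_csv(out_dir / "ground_truth.csv", index=False)
        return out_dir


def _participant_ids(config: CohortConfig) -> list[tuple[str, Group]]:
    out = []
    for group in Group:
        for i in range(config.group_sizes.get(group, 0)):
            out.append((f"{group.value}{i + 1:02d}", group))
    return out


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate the full cohort and its ground-truth table.

    The true mode for participant *i* of group *g* on task *t* is

        m_igt = scale_g * target_t + alpha_i + eps_igt   (floored at 1 deg/s)

    with alpha_i ~ N(0, participant_sd^2) and eps ~ N(0, residual_sd^2);
    each recording is calibrated so its processed velocity-norm mode equals
    m_igt within one bin.  The ground-truth table records m_igt (column
    ``cell_mode_velocity``) and the *realized* modes of the emitted noisy
    recording (``true_mode_velocity`` / ``true_mode_acceleration``), i.e.
    the quantities a perfect downstream recovery would reproduce.  Group
    ordering of overall dispersion (BV < UV < HS) holds by construction of
    the scale factors.
    """
    params = ProcessingParams()
    spec = HistogramSpec()
    master = np.random.default_rng(
        np.random.SeedSequence([config.seed & 0x7FFFFFFF, 0xC0F0])
    )
    participants = _participant_ids(config)
    alphas = {
        pid: master.normal(0.0, config.participant_sd) for pid, _ in participants
    }
    recordings: dict[tuple[str, Task], GyroRecording] = {}
    manifest_rows: list[ManifestRow] = []
    truth_rows = []
    for pid, group in participants:
        scale_g = config.group_scales[group]
        for task, profile in config.task_profiles.items():
            miss_p = config.missing_probability.get((group, task), 0.0)
            cell_rng = np.random.default_rng(
                _recording_seed(config.seed, pid, task)
            )
            if cell_rng.uniform() < miss_p:
                continue
            cell_mode = scale_g * profile.target_mode_velocity + alphas[pid]
            cell_mode += cell_rng.normal(0.0, config.residual_sd)
            cell_mode = max(cell_mode, 1.0)
            n = int(round(profile.duration_s * config.fs_hz))
            scaled, _, _ = _generate_calibrated(
                profile, cell_mode, config.fs_hz, cell_rng, pid, group,
                params, spec,
            )
            samples = scaled + _highfreq_noise(
                n, config.fs_hz, profile.noise_sd_highfreq, cell_rng
            )
            rec = GyroRecording(pid, group, task, config.fs_hz, samples)
            recordings[(pid, task)] = rec
            # realized (true) modes of the emitted recording itself
            final = process_recording(rec, params)
            mode_v = histogram_mode(
                final.velocity_norm, spec.bin_width_velocity, spec.origin
            )
            mode_a = histogram_mode(
                final.acceleration_norm, spec.bin_width_acceleration, spec.origin
            )
            fname = f"{pid}_{task.value.replace(' ', '_')}.csv"
            manifest_rows.append(ManifestRow(pid, group, task, fname, config.fs_hz))
            truth_rows.append(
                {
                    "participant_id": pid,
                    "group": group.value,
                    "task": task.value,
                    "cell_mode_velocity": cell_mode,
                    "true_mode_velocity": mode_v,
                    "true_mode_acceleration": mode_a,
                    "group_scale": scale_g,
                }
            )
    return SyntheticCohort(
        config=config,
        manifest=CohortManifest(manifest_rows),
        recordings=recordings,
        ground_truth=pd.DataFrame(truth_rows),
    )


def implied_cell_means(config: CohortConfig) -> pd.DataFrame:
    """Expected cell-mean velocity mode for every (group, task)."""
    rows = [
        {
            "group": g.value,
            "task": t.value,
            "mean_mode_velocity": config.group_scales[g] * p.target_mode_velocity,
        }
        for g in Group
        if config.group_sizes.get(g, 0) > 0
        for t, p in config.task_profiles.items()
    ]
    return pd.DataFrame(rows)


def implied_fixed_effects(
    config: CohortConfig,
    ref_group: Group = Group.HS,
    ref_task: Task = Task.WALK,
) -> dict[str, float]:
    """True treatment-coded fixed effects implied by the scale factors.

    With cell means scale_g * target_t the implied coefficients are exactly
    the reference-coded contrasts of those means.
    """
    s = config.group_scales
    m = {t: p.target_mode_velocity for t, p in config.task_profiles.items()}
    out = {"Intercept": s[ref_group] * m[ref_task]}
    groups = [g for g in Group if g is not ref_group and config.group_sizes.get(g, 0) > 0]
    tasks = [t for t in config.task_profiles if t is not ref_task]
    for g in groups:
        out[f"group[{g.value}]"] = (s[g] - s[ref_group]) * m[ref_task]
    for t in tasks:
        out[f"task[{t.value}]"] = s[ref_group] * (m[t] - m[ref_task])
    for t in tasks:
        for g in groups:
            out[f"group[{g.value}]:task[{t.value}]"] = (s[g] - s[ref_group]) * (
                m[t] - m[ref_task]
            )
    return out


#: Per-(group, task-category) rating probabilities (easy, medium, difficult),
#: qualitatively mirroring the reported perception patterns: BV finds the
#: Wood beam and Inclined plane difficult, HS finds the Wood beam uniformly
#: easy, UV sits in between.
_RATING_TABLES: dict[Group, dict[Task | None, tuple[float, float, float]]] = {
    Group.BV: {
        Task.WOOD_BEAM: (0.06, 0.33, 0.61),
        Task.INCLINED_PLANE: (0.08, 0.20, 0.72),
        Task.WALK_IN_THE_DARK: (0.43, 0.40, 0.17),
        None: (0.45, 0.40, 0.15),
    },
    Group.UV: {
        Task.WOOD_BEAM: (0.18, 0.35, 0.47),
        Task.INCLINED_PLANE: (0.28, 0.40, 0.32),
        None: (0.60, 0.30, 0.10),
    },
    Group.HS: {
        Task.WOOD_BEAM: (1.0, 0.0, 0.0),
        None: (0.85, 0.13, 0.02),
    },
}


def generate_ratings(
    config: CohortConfig, cohort: SyntheticCohort, seed: int | None = None
) -> list[DifficultyRating]:
    """Draw per-cell difficulty ratings consistent with the cohort.

    Cells absent from the cohort (participant unable to perform) are rated
    "unable"; present cells draw easy/medium/difficult from per-group
    categorical tables.  Deterministic given the seed (defaults to the
    cohort master seed).
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xA71]))
    ratings: list[DifficultyRating] = []
    levels = [Rating.EASY, Rating.MEDIUM, Rating.DIFFICULT]
    for pid, group in _participant_ids(config):
        table = _RATING_TABLES[group]
        for task in config.task_profiles:
            if (pid, task) not in cohort.recordings:
                ratings.append(DifficultyRating(pid, task, Rating.UNABLE))
                continue
            probs = np.array(table.get(task, table[None]))
            choice = rng.choice(3, p=probs / probs.sum())
            ratings.append(DifficultyRating(pid, task, levels[choice]))
    return ratings
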