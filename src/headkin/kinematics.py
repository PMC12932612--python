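"""Gyroscope signal conditioning and kinematic derivation.

The processing chain for each recording, in order:

1. trim the first and last 5% of samples (start-up and wind-down artefacts);
2. zero-phase low-pass Butterworth filter (per-pass order 4, cutoff 6 Hz)
   applied to each angular-velocity component;
3. Euclidean norm across the three components — the overall rotational
   intensity, independent of movement direction and of sensor alignment;
4. central-difference temporal derivative of the *filtered* velocity
   components, filtered again with the same low-pass, then the norm —
   the angular-acceleration intensity.

The filter is applied forward and backward (:func:`scipy.signal.filtfilt`)
so velocity and the derived acceleration stay phase-aligned; the effective
magnitude response is the square of the single-pass Butterworth response
(gain 0.5 at the cutoff).  The cutoff is not pre-warped for the dual pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import DegenerateInputError, ParameterError, ShapeError
from .imu_io import Group, GyroRecording, Task

__all__ = [
    "ProcessingParams",
    "KinematicSeries",
    "trim_edges",
    "butter_lowpass",
    "vector_norm",
    "differentiate",
    "process_recording",
]


@dataclass(frozen=True)
class ProcessingParams:
    """Signal-chain parameters.

    Defaults follow the study protocol: 5% edge trim, 6 Hz cutoff,
    4th-order Butterworth, central differences.
    """

    trim_fraction: float = 0.05
    cutoff_hz: float = 6.0
    filter_order: int = 4
    derivative_scheme: str = "central"  # {"central", "forward"}

    def __post_init__(self) -> None:
        if not 0.0 <= self.trim_fraction < 0.5:
            raise ParameterError("trim_fraction must lie in [0, 0.5)")
        if not self.cutoff_hz > 0:
            raise ParameterError("cutoff_hz must be positive")
        if not (isinstance(self.filter_order, int) and self.filter_order >= 1):
            raise ParameterError("filter_order must be a positive integer")
        if self.derivative_scheme not in ("central", "forward"):
            raise ParameterError("derivative_scheme must be 'central' or 'forward'")


@dataclass
class KinematicSeries:
    """Processed per-recording velocity-norm and acceleration-norm series."""

    participant_id: str
    group: Group
    task: Task
    fs_hz: float
    velocity_norm: np.ndarray  # deg/s
    acceleration_norm: np.ndarray  # deg/s^2

    def __post_init__(self) -> None:
        self.velocity_norm = np.asarray(self.velocity_norm, dtype=float)
        self.acceleration_norm = np.asarray(self.acceleration_norm, dtype=float)
        if self.velocity_norm.shape != self.acceleration_norm.shape:
            raise ShapeError("velocity and acceleration norms must have equal length")
        for name in ("velocity_norm", "acceleration_norm"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ShapeError(f"{name} must be finite and non-negative")


def trim_edges(samples: np.ndarray, fraction: float) -> np.ndarray:
    """Remove ``floor(fraction * T)`` samples from each end of the series."""
    if not 0.0 <= fraction < 0.5:
        raise ParameterError("trim fraction must lie in [0, 0.5)")
    samples = np.asarray(samples)
    n = samples.shape[0]
    k = int(np.floor(fraction * n))
    kept = n - 2 * k
    if kept < 2:
        raise DegenerateInputError(
            f"trimming {k} samples per side of {n} leaves fewer than 2"
        )
    return samples[k : n - k]


def butter_lowpass(
    samples: np.ndarray, fs_hz: float, cutoff_hz: float, order: int = 4
) -> np.ndarray:
    """Column-wise zero-phase Butterworth low-pass filter.

    Forward-backward application (odd-reflection padding, pad length
    3 x the filter state length); linear, DC gain exactly 1.
    """
    if not cutoff_hz < fs_hz / 2:
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz must be below the Nyquist rate {fs_hz / 2} Hz"
        )
    samples = np.asarray(samples, dtype=float)
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs_hz, output="sos")
    # filtfilt default padlen for sos is 3 * (n_sections * 2); require margin.
    padlen = 3 * (2 * sos.shape[0])
    if samples.shape[0] <= padlen:
        raise DegenerateInputError(
            f"series of length {samples.shape[0]} too short for stable "
            f"bidirectional filtering (needs > {padlen})"
        )
    return signal.sosfiltfilt(sos, samples, axis=0)


def vector_norm(samples: np.ndarray) -> np.ndarray:
    """Elementwise Euclidean norm of a T x 3 matrix (rotation invariant)."""
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 3:
        raise ShapeError(f"expected a T x 3 matrix, got shape {samples.shape}")
    return np.linalg.norm(samples, axis=1)


def differentiate(
    samples: np.ndarray, fs_hz: float, scheme: str = "central"
) -> np.ndarray:
    """Per-column temporal derivative, in units/s; output length = input length.

    ``central``: (x[i+1] - x[i-1]) * fs / 2 in the interior, one-sided
    differences at the endpoints (exact for linear signals).
    ``forward``: (x[i+1] - x[i]) * fs, last row repeated.
    """
    samples = np.asarray(samples, dtype=float)
    n = samples.shape[0]
    if scheme == "central":
        if n < 3:
            raise DegenerateInputError("central differences need at least 3 samples")
        return np.gradient(samples, axis=0) * fs_hz
    if scheme == "forward":
        if n < 2:
            raise DegenerateInputError("forward differences need at least 2 samples")
        d = np.diff(samples, axis=0) * fs_hz
        return np.concatenate([d, d[-1:]], axis=0)
    raise ParameterError(f"unknown derivative scheme {scheme!r}")


def process_recording(
    rec: GyroRecording, params: ProcessingParams | None = None
) -> KinematicSeries:
    """Run the full signal chain on one recording.

    trim -> low-pass -> norm (velocity); derivative of the filtered
    components -> low-pass -> norm (acceleration).
    """
    if params is None:
        params = ProcessingParams()
    fs = rec.sampling_rate_hz
    trimmed = trim_edges(rec.samples, params.trim_fraction)
    vel = butter_lowpass(trimmed, fs, params.cutoff_hz, params.filter_order)
    velocity_norm = vector_norm(vel)
    acc = differentiate(vel, fs, params.derivative_scheme)
    acc = butter_lowpass(acc, fs, params.cutoff_hz, params.filter_order)
    acceleration_norm = vector_norm(acc)
    return KinematicSeries(
        participant_id=rec.participant_id,
        group=rec.group,
        task=rec.task,
        fs_hz=fs,
        velocity_norm=velocity_norm,
        acceleration_norm=acceleration_norm,
    )
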