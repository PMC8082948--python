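"""Core record types for smartwatch inertial data.

A recording is a continuous 9-channel trace from a wrist-worn device:
triaxial accelerometer (m/s^2), triaxial gyroscope (rad/s) and triaxial
magnetometer (uT), uniformly sampled (50 Hz in the study design this
package models). Label spans mark supervised exercise bouts within a
recording, in seconds from its start, end-exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np

#: Fixed channel order for every T x 9 sample matrix.
CHANNELS = ("ax", "ay", "az", "gx", "gy", "gz", "mx", "my", "mz")

N_CHANNELS = len(CHANNELS)

#: Standard gravity mixed into accelerometer channels (m/s^2).
GRAVITY_MS2 = 9.81


@dataclass
class ImuRecording:
    """One continuous 9-channel inertial trace with session metadata.

    Parameters
    ----------
    patient_id, session_id
        Identifiers linking the trace to a patient and session.
    setting
        ``"home"`` or ``"clinic"``; clinic sessions are supervised.
    start_datetime
        Local wall-clock time of the first sample.
    sample_rate_hz
        Uniform sampling rate; the study hardware records at 50 Hz.
    samples
        ``(T, 9)`` float array in :data:`CHANNELS` order.
    """

    patient_id: str
    session_id: str
    setting: str
    start_datetime: datetime
    sample_rate_hz: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != N_CHANNELS:
            raise ValueError(
                f"samples must be (T, {N_CHANNELS}), got {self.samples.shape}"
            )
        if self.samples.shape[0] < 1:
            raise ValueError("recording must contain at least one sample")
        if not np.isfinite(self.samples).all():
            raise ValueError("recording contains non-finite samples")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.setting not in ("home", "clinic"):
            raise ValueError(f"setting must be 'home' or 'clinic', got {self.setting!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def time_at(self, offset_s: float) -> datetime:
        """Wall-clock time at an offset (seconds) into the recording."""
        return self.start_datetime + timedelta(seconds=offset_s)


@dataclass(frozen=True)
class LabelSpan:
    """A labeled interval within a recording: [start_s, end_s) seconds."""

    start_s: float
    end_s: float
    class_id: int
    repetitions: int = 0

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("span end must be after start")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def concat_recordings(parts: list[np.ndarray]) -> np.ndarray:
    """Concatenate sample blocks along time, validating channel count."""
    for p in parts:
        if p.ndim != 2 or p.shape[1] != N_CHANNELS:
            raise ValueError("every block must be (T, 9)")
    return np.concatenate(parts, axis=0)
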