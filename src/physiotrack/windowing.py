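"""Sliding-window segmentation, label simplification and temporal splitting.

Raw recordings become fixed-length windows (10 s by default — the
classifier's unit of input), each labeled with the principal-motion class
of the exercise span that covers most of it. Train/test partitioning is
temporal and per patient: every patient's chronologically last session is
held out, so evaluation mimics deployment on future sessions rather than
shuffled windows of already-seen ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np

from .records import ImuRecording, LabelSpan

logger = logging.getLogger(__name__)

UNLABELED = -1


@dataclass
class Window:
    """One fixed-length multichannel segment cut from a recording."""

    patient_id: str
    session_id: str
    setting: str
    start_s: float
    length_s: float
    values: np.ndarray  # (L, C)
    label: int = UNLABELED
    center_datetime: datetime | None = None

    @property
    def end_s(self) -> float:
        return self.start_s + self.length_s


@dataclass(frozen=True)
class MotionClassMap:
    """Total mapping from protocol exercise ids to principal-motion classes.

    Collapses a many-exercise protocol onto the smaller set of principal
    motions the classifier is trained on (several exercises share the
    same dominant movement). ADL ids pass through unchanged.
    """

    table: dict[int, int]

    def __call__(self, exercise_id: int) -> int:
        if exercise_id not in self.table:
            raise KeyError(f"exercise id {exercise_id} missing from motion class map")
        return self.table[exercise_id]

    @classmethod
    def identity(cls, ids) -> "MotionClassMap":
        return cls({int(i): int(i) for i in ids})


def segment_windows(
    recording: ImuRecording,
    window_s: float = 10.0,
    stride_s: float = 5.0,
) -> list[Window]:
    """Cut a recording into overlapping fixed-length windows.

    Windows start at 0, ``stride_s``, 2*stride_s, ... and never span the
    recording boundary; a recording shorter than one window yields an
    empty list. For a recording of T samples, window length L and stride
    S samples, the count is ``floor((T - L) / S) + 1``.
    """
    if stride_s <= 0:
        raise ValueError("stride_s must be positive")
    L_f = window_s * recording.sample_rate_hz
    L = int(round(L_f))
    if abs(L_f - L) > 1e-9:
        raise ValueError("window_s x sample_rate_hz must be an integer")
    S = int(round(stride_s * recording.sample_rate_hz))
    if S < 1:
        raise ValueError("stride shorter than one sample")
    T = recording.n_samples
    out: list[Window] = []
    for start in range(0, T - L + 1, S):
        start_s = start / recording.sample_rate_hz
        out.append(Window(
            patient_id=recording.patient_id,
            session_id=recording.session_id,
            setting=recording.setting,
            start_s=start_s,
            length_s=window_s,
            values=recording.samples[start:start + L],
            center_datetime=recording.time_at(start_s + window_s / 2),
        ))
    return out


def assign_labels(
    windows: list[Window],
    spans: list[LabelSpan],
    class_map: MotionClassMap,
    occupancy_threshold: float = 0.5,
    background_class: int | None = None,
) -> list[Window]:
    """Label windows with the mapped class covering most of each window.

    A window takes the principal-motion class of the single span covering
    strictly more than ``occupancy_threshold`` of it; otherwise it is
    left ``UNLABELED`` (excluded from training sets), or assigned
    ``background_class`` when given — used for ADL recordings where
    un-spanned time *is* the recording's activity. Spans must be
    non-overlapping; the result does not depend on their order.
    """
    for a in spans:
        for b in spans:
            if a is not b and a.start_s < b.end_s and b.start_s < a.end_s:
                raise ValueError("label spans overlap")
    labeled = []
    for w in windows:
        cover: dict[int, float] = {}
        for sp in spans:
            ov = min(w.end_s, sp.end_s) - max(w.start_s, sp.start_s)
            if ov > 0:
                cls = class_map(sp.class_id)
                cover[cls] = cover.get(cls, 0.0) + ov
        label = UNLABELED if background_class is None else background_class
        if cover:
            best = max(sorted(cover), key=lambda c: cover[c])
            if cover[best] > occupancy_threshold * w.length_s:
                label = best
            else:
                label = UNLABELED
        labeled.append(Window(w.patient_id, w.session_id, w.setting,
                              w.start_s, w.length_s, w.values, label,
                              w.center_datetime))
    return labeled


def temporal_split(
    sessions: list[tuple[str, str, datetime, list[Window]]],
    adl_sessions: list[tuple[str, list[Window]]] | None = None,
    adl_to_test: bool = False,
) -> tuple[list[Window], list[Window]]:
    """Per-patient chronological train/test split.

    ``sessions`` is ``(patient_id, session_id, start_datetime, windows)``.
    Each patient's chronologically last session goes to test; all earlier
    sessions go to train. Patients with a single session contribute to
    test only (logged, so cohort builders can require >= 2 sessions).
    Duplicate timestamps within a patient are broken deterministically by
    session_id, with a warning. ADL recordings (from healthy volunteers,
    used to augment the exercise data with daily-living negatives) are
    routed wholesale to train or test by ``adl_to_test``.
    """
    by_patient: dict[str, list] = {}
    for pid, sid, dt, wins in sessions:
        by_patient.setdefault(pid, []).append((dt, sid, wins))
    train: list[Window] = []
    test: list[Window] = []
    for pid, items in by_patient.items():
        times = [dt for dt, _, _ in items]
        if len(set(times)) < len(times):
            logger.warning("patient %s has duplicate session timestamps; "
                           "breaking ties by session_id", pid)
        items.sort(key=lambda x: (x[0], x[1]))
        if len(items) == 1:
            logger.info("patient %s has a single session; it goes to test "
                        "and contributes no training data", pid)
        for dt, sid, wins in items[:-1]:
            train.extend(wins)
        test.extend(items[-1][2])
    for pid, wins in (adl_sessions or []):
        (test if adl_to_test else train).extend(wins)
    return train, test


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

@dataclass
class ChannelScaler:
    """Per-channel z-scoring with statistics from the training split only."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, windows: list[Window]) -> "ChannelScaler":
        if not windows:
            raise ValueError("cannot fit scaler on an empty window set")
        stacked = np.concatenate([w.values for w in windows], axis=0)
        std = stacked.std(axis=0)
        std[std == 0] = 1.0
        return cls(mean=stacked.mean(axis=0), std=std)

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (values - self.mean) / self.std


def windows_to_arrays(
    windows: list[Window],
    scaler: ChannelScaler | None = None,
    drop_unlabeled: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack windows into (N, L, C) values and (N,) integer labels."""
    use = [w for w in windows if not (drop_unlabeled and w.label == UNLABELED)]
    if not use:
        return (np.empty((0, 0, 0)), np.empty((0,), dtype=int))
    X = np.stack([w.values for w in use]).astype(np.float32)
    if scaler is not None:
        X = ((X - scaler.mean[None, None, :]) / scaler.std[None, None, :]
             ).astype(np.float32)
    y = np.array([w.label for w in use], dtype=int)
    return X, y
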