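"""The default seeded synthetic classifier benchmark.

A fixed, reproducible desk-scale stand-in for clinical validation of the
activity classifier: 5 synthetic patients x 5 supervised sessions, each
session containing one 60-second bout of every one of the 7 exercise
classes, plus healthy-volunteer ADL recordings of all 4 daily-living
classes routed to train and test. Splitting is temporal (each patient's
last session held out), windows are 10 s with 50% training overlap and
non-overlapping at test time, and channels are z-scored on the training
split only. This yields ~220 training windows per class.

Both evaluation tasks are covered: binary exercise-vs-ADL detection and
multiclass exercise recognition (trained and scored on exercise windows).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np

from .fcn import FcnClassifier, FcnConfig
from .metrics import ClassifierMetrics, binarize_labels, evaluate
from .records import ImuRecording
from .simulate import (default_motion_classes, gen_adl_recording,
                       gen_session)
from .windowing import (ChannelScaler, MotionClassMap, UNLABELED,
                        assign_labels, segment_windows, temporal_split,
                        windows_to_arrays)

#: FCN sized for single-CPU NumPy training on the benchmark; the input is
#: block-decimated 8x so the conv stack's receptive field spans a full
#: repetition period of the slowest exercise.
BENCHMARK_FCN = dict(conv_blocks=((32, 8), (64, 5), (32, 3)),
                     epochs=30, patience=10, downsample=8)


@dataclass
class BenchmarkData:
    X_train: np.ndarray
    y_train: np.ndarray
    groups_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    scaler: ChannelScaler
    exercise_ids: list[int]


def make_benchmark(
    seed: int,
    n_patients: int = 5,
    sessions_per_patient: int = 5,
    bout_s: float = 60.0,
    adl_recordings_per_class: int = 4,
    adl_duration_s: float = 360.0,
    train_stride_s: float = 5.0,
) -> BenchmarkData:
    """Generate the benchmark windows under temporal splitting."""
    classes = default_motion_classes()
    ex_ids = sorted(c.class_id for c in classes.values() if c.kind == "exercise")
    adl_ids = sorted(c.class_id for c in classes.values() if c.kind == "adl")
    cmap = MotionClassMap.identity(list(classes))
    rng = np.random.default_rng(seed)

    sessions = []
    for p in range(n_patients):
        for s in range(sessions_per_patient):
            rec, spans = gen_session(
                [(i, bout_s) for i in ex_ids], rest_gap_s=20.0,
                seed=int(rng.integers(2**31)),
                patient_id=f"bench{p}", session_id=f"bench{p}_s{s}",
                start_datetime=datetime(2021, 1, 4, 10, 0) + timedelta(days=s))
            wins = assign_labels(segment_windows(rec, 10.0, train_stride_s),
                                 spans, cmap)
            sessions.append((f"bench{p}", f"bench{p}_s{s}",
                             rec.start_datetime, wins))

    adl_train, adl_test = [], []
    for aid in adl_ids:
        for j in range(adl_recordings_per_class):
            sig = gen_adl_recording(classes[aid], adl_duration_s, 50.0,
                                    seed=int(rng.integers(2**31)))
            rec = ImuRecording(
                patient_id=f"vol{aid}_{j}", session_id=f"adl{aid}_{j}",
                setting="home", start_datetime=datetime(2021, 1, 4, 12, 0),
                sample_rate_hz=50.0, samples=sig)
            wins = assign_labels(segment_windows(rec, 10.0, train_stride_s),
                                 [], cmap, background_class=aid)
            # last volunteer recording of each class held out, like the
            # study's separate test volunteers
            dest = adl_test if j == adl_recordings_per_class - 1 else adl_train
            dest.append((rec.patient_id, wins))

    train_w, test_w = temporal_split(sessions, adl_train, adl_to_test=False)
    _, test_adl = temporal_split([], adl_test, adl_to_test=True)
    test_w = test_w + test_adl

    scaler = ChannelScaler.fit([w for w in train_w if w.label != UNLABELED])
    Xtr, ytr = windows_to_arrays(train_w, scaler)
    Xte, yte = windows_to_arrays(test_w, scaler)
    gtr = np.array([w.patient_id for w in train_w if w.label != UNLABELED])
    return BenchmarkData(Xtr, ytr, gtr, Xte, yte, scaler, ex_ids)


def oracle_prediction_series(recording, spans, window_s: float = 10.0):
    """Build a PredictionSeries from ground-truth labels (oracle classifier).

    Windows the recording non-overlappingly and predicts 1 wherever an
    exercise span covers the majority of a window — the upper bound a
    perfect binary classifier could achieve. Used to validate that the
    participation roll-up recovers scheduled minutes up to window
    quantization at bout boundaries.
    """
    from .fcn import PredictionSeries

    classes = default_motion_classes()
    ex_ids = [c.class_id for c in classes.values() if c.kind == "exercise"]
    cmap = MotionClassMap.identity(list(classes))
    wins = segment_windows(recording, window_s, window_s)
    wins = assign_labels(wins, spans, cmap)
    pred = np.array([1 if w.label in ex_ids else 0 for w in wins])
    probs = np.stack([1.0 - pred, pred], axis=1).astype(float)
    return PredictionSeries(
        recording.patient_id, recording.session_id, recording.setting,
        window_s, np.array([w.start_s for w in wins]),
        [recording.time_at(w.start_s) for w in wins],
        probs, np.array([0, 1]), pred)


def run_benchmark(seed: int, data: BenchmarkData | None = None
                  ) -> tuple[ClassifierMetrics, ClassifierMetrics, dict]:
    """Train both models on the benchmark and score the temporal test set.

    Returns (binary metrics, multiclass metrics, trained models dict).
    """
    if data is None:
        data = make_benchmark(seed)
    n_ch = data.X_train.shape[2]

    ybin_tr = binarize_labels(data.y_train, data.exercise_ids)
    binary = FcnClassifier(FcnConfig(input_channels=n_ch, n_classes=2,
                                     seed=seed, **BENCHMARK_FCN))
    binary.fit(data.X_train, ybin_tr, groups=data.groups_train)
    ybin_te = binarize_labels(data.y_test, data.exercise_ids)
    proba = binary.predict_proba(data.X_test)
    pos = int(np.where(binary.classes_ == 1)[0][0])
    m_bin = evaluate(ybin_te, binary.predict(data.X_test), "binary",
                     proba_positive=proba[:, pos])

    ex_tr = ybin_tr == 1
    multi = FcnClassifier(FcnConfig(input_channels=n_ch,
                                    n_classes=len(data.exercise_ids),
                                    seed=seed, **BENCHMARK_FCN))
    multi.fit(data.X_train[ex_tr], data.y_train[ex_tr],
              groups=data.groups_train[ex_tr])
    ex_te = ybin_te == 1
    m_multi = evaluate(data.y_test[ex_te], multi.predict(data.X_test[ex_te]),
                       "multiclass", labels=multi.classes_)
    return m_bin, m_multi, {"binary": binary, "multiclass": multi}
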