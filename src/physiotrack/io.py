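"""Plain-text file dialects for recordings, labels and cohort tables.

* IMU CSV: ``t_s, ax, ay, az, gx, gy, gz, mx, my, mz`` one row per
  sample, with a JSON sidecar (same stem, ``.meta.json``) carrying
  patient/session/setting metadata, the ISO-8601 local start time and
  the sample rate. Units: accelerometer m/s^2, gyroscope rad/s,
  magnetometer uT.
* Label CSV: ``start_s, end_s, class_id, repetitions`` (end exclusive,
  seconds from recording start).
* Cohort CSVs: ``baselines.csv``, ``outcomes.csv`` (long format),
  ``ground_truth_participation.csv``, ``sessions.csv``,
  ``assigned_days.csv``.
"""

from __future__ import annotations

import json
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .records import CHANNELS, ImuRecording, LabelSpan
from .simulate import SyntheticCohort

IMU_UNITS = {"accelerometer": "m/s^2", "gyroscope": "rad/s",
             "magnetometer": "uT"}


def write_imu_csv(recording: ImuRecording, path: str | Path) -> None:
    path = Path(path)
    t = np.arange(recording.n_samples) / recording.sample_rate_hz
    df = pd.DataFrame(recording.samples, columns=list(CHANNELS))
    df.insert(0, "t_s", t)
    df.to_csv(path, index=False, float_format="%.6g")
    meta = {
        "patient_id": recording.patient_id,
        "session_id": recording.session_id,
        "setting": recording.setting,
        "start_datetime": recording.start_datetime.isoformat(),
        "sample_rate_hz": recording.sample_rate_hz,
        "units": IMU_UNITS,
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))


def read_imu_csv(path: str | Path) -> ImuRecording:
    path = Path(path)
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    df = pd.read_csv(path)
    return ImuRecording(
        patient_id=meta["patient_id"],
        session_id=meta["session_id"],
        setting=meta["setting"],
        start_datetime=datetime.fromisoformat(meta["start_datetime"]),
        sample_rate_hz=float(meta["sample_rate_hz"]),
        samples=df[list(CHANNELS)].to_numpy(),
    )


def write_labels_csv(spans: list[LabelSpan], path: str | Path) -> None:
    pd.DataFrame(
        [(s.start_s, s.end_s, s.class_id, s.repetitions) for s in spans],
        columns=["start_s", "end_s", "class_id", "repetitions"],
    ).to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> list[LabelSpan]:
    df = pd.read_csv(path)
    return [LabelSpan(r.start_s, r.end_s, int(r.class_id), int(r.repetitions))
            for r in df.itertuples(index=False)]


def write_cohort_csvs(cohort: SyntheticCohort, outdir: str | Path) -> dict:
    """Write all cohort tables; returns {name: path}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    tables = {
        "baselines": cohort.baselines,
        "outcomes": cohort.outcomes,
        "ground_truth_participation": cohort.ground_truth,
        "sessions": cohort.sessions,
        "assigned_days": cohort.assigned,
        "true_participation": cohort.true_participation,
    }
    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths


def read_cohort_csvs(indir: str | Path) -> dict[str, pd.DataFrame]:
    indir = Path(indir)
    out = {}
    for name in ("baselines", "outcomes", "ground_truth_participation",
                 "sessions", "assigned_days", "true_participation"):
        p = indir / f"{name}.csv"
        if p.exists():
            df = pd.read_csv(p)
            if "date" in df.columns:
                df["date"] = pd.to_datetime(df["date"]).dt.date
            out[name] = df
    return out
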