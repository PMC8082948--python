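"""End-to-end orchestration: simulate -> prep -> train -> evaluate -> track -> analyze.

Each stage reads and writes declared files under a single run directory,
so stages can be re-run independently and a saved config reproduces a
run bit-compatibly for the deterministic stages:

```
run/
  manifest.json                 config hash, seed, versions, stage timings
  cohort/*.csv                  simulated cohort tables
  recordings/*.csv(.meta.json)  materialized IMU traces + label spans
  prep/windows.npz, windows_manifest.csv, scaler.npz
  models/binary.*, multiclass.*, training_log.csv
  reports/metrics.json
  track/daily_participation.csv, weekly_summary.csv, patterns_*.csv
  analysis/dose_response.csv, predictors.csv, report.txt
```

The cohort-level analysis defaults to the scheduled ground-truth
participation table (recordings are only materialized for a configurable
subset of patients; classifying a full 12-week cohort at 50 Hz is a
compute exercise, not an analysis one). Set ``analysis.source:
detected`` to analyze classifier-detected minutes instead.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as ptio
from .fcn import FcnClassifier, FcnConfig, predict_recording
from .metrics import binarize_labels, evaluate
from .outcomes import (DASH_MCID, NPRS_MCID_RANGE, cumulative_participation,
                       dose_response, improvement, mcid_threshold,
                       predictor_analysis, proportions)
from .participation import (adherent_days_fraction, daily_rollup,
                            extract_bouts, phase_comparison,
                            temporal_patterns, weekly_minutes, ExerciseBout)
from .records import LabelSpan
from .simulate import (ADL_COMPUTER, ADL_HOUSEHOLD, ADL_REST, ADL_WALK,
                       CohortSimConfig, default_motion_classes,
                       gen_adl_recording, gen_cohort, iter_session_recordings)
from .windowing import (ChannelScaler, MotionClassMap, UNLABELED,
                        assign_labels, segment_windows, temporal_split,
                        windows_to_arrays)

logger = logging.getLogger(__name__)

STAGES = ("prep", "train", "evaluate", "track", "analyze")
ADL_IDS = (ADL_REST, ADL_WALK, ADL_COMPUTER, ADL_HOUSEHOLD)


@dataclass
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    cohort: dict = field(default_factory=dict)
    recordings: dict = field(default_factory=lambda: {
        "patients": 4, "max_sessions_per_patient": 3,
        "adl_train": 4, "adl_test": 2, "adl_duration_s": 300.0})
    windows: dict = field(default_factory=lambda: {
        "window_s": 10.0, "train_stride_s": 5.0, "infer_stride_s": 10.0,
        "occupancy_threshold": 0.5})
    fcn: dict = field(default_factory=lambda: {
        "conv_blocks": [[32, 8], [64, 5], [32, 3]], "epochs": 12,
        "batch_size": 64, "learning_rate": 1e-3, "downsample": 8})
    participation: dict = field(default_factory=lambda: {
        "expectation_min": 20.0, "min_bout_s": 60.0, "smoothing_width": 3,
        "session_gap_min": 30.0})
    analysis: dict = field(default_factory=lambda: {
        "timepoints": [4, 8, 12], "source": "ground_truth"})
    verbosity: str = "info"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        base = cls()
        kwargs = {}
        for f in dataclasses.fields(cls):
            v = d.get(f.name, getattr(base, f.name))
            if isinstance(getattr(base, f.name), dict) and f.name in d:
                merged = dict(getattr(base, f.name))
                merged.update(d[f.name])
                v = merged
            kwargs[f.name] = v
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _out(cfg: RunConfig) -> Path:
    return Path(cfg.out_dir)


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs {path}, produced by stage '{produced_by}'")
    return path


def _update_manifest(cfg: RunConfig, stage: str, seconds: float,
                     extra: dict | None = None) -> None:
    path = _out(cfg) / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {
        "config": cfg.to_dict(), "config_hash": cfg.config_hash(),
        "seed": cfg.seed, "stages": {}}
    manifest["stages"][stage] = {"wall_time_s": round(seconds, 2),
                                 **(extra or {})}
    path.write_text(json.dumps(manifest, indent=2, default=str))


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def run_simulate(cfg: RunConfig, force: bool = False) -> dict:
    """Write the synthetic dataset: cohort tables + a recording subset."""
    t0 = _time.time()
    out = _out(cfg)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(
            f"output directory {out} is not empty; pass force=True/--force")
    (out / "cohort").mkdir(parents=True, exist_ok=True)
    (out / "recordings").mkdir(exist_ok=True)

    ckw = dict(cfg.cohort)
    ckw.setdefault("seed", cfg.seed)
    cohort_cfg = CohortSimConfig(**ckw)
    cohort = gen_cohort(cohort_cfg)
    ptio.write_cohort_csvs(cohort, out / "cohort")

    # materialize recordings for a subset of patients / sessions
    rcfg = cfg.recordings
    pids = sorted(cohort.sessions.patient_id.unique())[:rcfg["patients"]]
    n_written = 0
    kept: dict[str, int] = {p: 0 for p in pids}
    for rec, spans in iter_session_recordings(cohort, patient_ids=pids):
        if kept[rec.patient_id] >= rcfg["max_sessions_per_patient"]:
            continue
        kept[rec.patient_id] += 1
        stem = out / "recordings" / rec.session_id
        ptio.write_imu_csv(rec, stem.with_suffix(".csv"))
        ptio.write_labels_csv(spans, Path(str(stem) + ".labels.csv"))
        n_written += 1

    # healthy-volunteer ADL recordings for augmentation
    classes = default_motion_classes()
    rng = np.random.default_rng(cfg.seed + 1)
    from datetime import datetime
    for split, count in (("train", rcfg["adl_train"]), ("test", rcfg["adl_test"])):
        for i in range(count):
            adl_id = ADL_IDS[i % len(ADL_IDS)]
            sig = gen_adl_recording(classes[adl_id], rcfg["adl_duration_s"],
                                    50.0, seed=int(rng.integers(2**31)))
            from .records import ImuRecording
            rec = ImuRecording(
                patient_id=f"vol_{split}_{i}", session_id=f"adl_{split}_{i}",
                setting="home", start_datetime=datetime(2021, 1, 4, 12, 0),
                sample_rate_hz=50.0, samples=sig)
            stem = out / "recordings" / rec.session_id
            ptio.write_imu_csv(rec, stem.with_suffix(".csv"))
            meta = json.loads(stem.with_suffix(".meta.json").read_text())
            meta.update({"adl_class": adl_id, "adl_split": split})
            stem.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))
            n_written += 1

    _update_manifest(cfg, "simulate", _time.time() - t0, {
        "patients": len(cohort.baselines), "recordings_written": n_written})
    return {"cohort_dir": out / "cohort", "recordings_dir": out / "recordings"}


# ---------------------------------------------------------------------------
# prep
# ---------------------------------------------------------------------------

def _load_recordings(recdir: Path):
    sessions, adl = [], []
    for csv in sorted(recdir.glob("*.csv")):
        if csv.name.endswith(".labels.csv"):
            continue
        meta = json.loads(csv.with_suffix(".meta.json").read_text())
        rec = ptio.read_imu_csv(csv)
        if "adl_class" in meta:
            adl.append((rec, int(meta["adl_class"]), meta["adl_split"]))
        else:
            spans = ptio.read_labels_csv(Path(str(csv.with_suffix("")) + ".labels.csv"))
            sessions.append((rec, spans))
    return sessions, adl


def run_prep(cfg: RunConfig) -> Path:
    """Window + label recordings, temporal split, z-scoring, manifest."""
    t0 = _time.time()
    out = _out(cfg)
    recdir = _require(out / "recordings", "prep", "simulate")
    wcfg = cfg.windows
    class_map = MotionClassMap.identity(
        [c for c in default_motion_classes()])
    sessions, adl = _load_recordings(recdir)
    if not sessions:
        raise FileNotFoundError(
            "stage 'prep' found no session recordings under "
            f"{recdir}; run stage 'simulate' first")

    sess_windows = []
    for rec, spans in sessions:
        wins = segment_windows(rec, wcfg["window_s"], wcfg["train_stride_s"])
        wins = assign_labels(wins, spans, class_map,
                             wcfg["occupancy_threshold"])
        sess_windows.append((rec.patient_id, rec.session_id,
                             rec.start_datetime, wins))
    adl_train, adl_test = [], []
    for rec, adl_id, split in adl:
        wins = segment_windows(rec, wcfg["window_s"], wcfg["train_stride_s"])
        wins = assign_labels(wins, [], class_map, background_class=adl_id)
        (adl_train if split == "train" else adl_test).append(
            (rec.patient_id, wins))

    train_w, test_w = temporal_split(sess_windows, adl_train, adl_to_test=False)
    _, test_adl = temporal_split([], adl_test, adl_to_test=True)
    test_w = test_w + test_adl

    train_lab = [w for w in train_w if w.label != UNLABELED]
    scaler = ChannelScaler.fit(train_lab)
    Xtr, ytr = windows_to_arrays(train_w, scaler)
    Xte, yte = windows_to_arrays(test_w, scaler)
    gtr = np.array([w.patient_id for w in train_w if w.label != UNLABELED])

    prep = out / "prep"
    prep.mkdir(exist_ok=True)
    np.savez_compressed(prep / "windows.npz", X_train=Xtr, y_train=ytr,
                        groups_train=gtr, X_test=Xte, y_test=yte)
    np.savez(prep / "scaler.npz", mean=scaler.mean, std=scaler.std)
    rows = []
    for split, wins in (("train", train_w), ("test", test_w)):
        for k, w in enumerate(wins):
            rows.append((f"{split}_{k}", w.session_id, w.start_s, w.label, split))
    pd.DataFrame(rows, columns=["window_id", "recording_id", "start_s",
                                "label", "split"]).to_csv(
        prep / "windows_manifest.csv", index=False)
    _update_manifest(cfg, "prep", _time.time() - t0,
                     {"n_train": len(ytr), "n_test": len(yte)})
    return prep


# ---------------------------------------------------------------------------
# train / evaluate
# ---------------------------------------------------------------------------

def _fcn_config(cfg: RunConfig, n_classes: int, n_channels: int) -> FcnConfig:
    f = cfg.fcn
    return FcnConfig(
        conv_blocks=tuple(tuple(b) for b in f["conv_blocks"]),
        input_channels=n_channels, n_classes=n_classes,
        epochs=f.get("epochs", 12), batch_size=f.get("batch_size", 64),
        learning_rate=f.get("learning_rate", 1e-3),
        val_fraction=f.get("val_fraction", 0.15),
        patience=f.get("patience", 6),
        downsample=f.get("downsample", 1), seed=cfg.seed)


def run_train(cfg: RunConfig) -> Path:
    """Train the binary exercise detector and the multiclass exercise model."""
    t0 = _time.time()
    out = _out(cfg)
    npz = _require(out / "prep" / "windows.npz", "train", "prep")
    data = np.load(npz, allow_pickle=False)
    Xtr, ytr = data["X_train"], data["y_train"]
    gtr = data["groups_train"]
    models = out / "models"
    models.mkdir(exist_ok=True)

    exercise_ids = [c.class_id for c in default_motion_classes().values()
                    if c.kind == "exercise"]
    ybin = binarize_labels(ytr, exercise_ids)
    binary = FcnClassifier(_fcn_config(cfg, 2, Xtr.shape[2]))
    binary.fit(Xtr, ybin, groups=gtr)
    binary.save(models / "binary")

    ex_mask = ybin == 1
    n_ex_classes = len(np.unique(ytr[ex_mask]))
    multi = FcnClassifier(_fcn_config(cfg, n_ex_classes, Xtr.shape[2]))
    multi.fit(Xtr[ex_mask], ytr[ex_mask], groups=gtr[ex_mask])
    multi.save(models / "multiclass")

    logs = []
    for name, model in (("binary", binary), ("multiclass", multi)):
        for rec in model.history:
            logs.append({"model": name, **rec})
    pd.DataFrame(logs).to_csv(models / "training_log.csv", index=False)
    _update_manifest(cfg, "train", _time.time() - t0, {
        "binary_params": binary.n_parameters(),
        "multiclass_params": multi.n_parameters()})
    return models


def run_evaluate(cfg: RunConfig) -> dict:
    """Score both models on the held-out temporal test set."""
    t0 = _time.time()
    out = _out(cfg)
    models = out / "models"
    _require(models / "binary.npz", "evaluate", "train")
    npz = _require(out / "prep" / "windows.npz", "evaluate", "prep")
    data = np.load(npz, allow_pickle=False)
    Xte, yte = data["X_test"], data["y_test"]
    if len(yte) == 0:
        raise ValueError("empty test set")
    exercise_ids = [c.class_id for c in default_motion_classes().values()
                    if c.kind == "exercise"]

    binary = FcnClassifier.load(models / "binary")
    ybin = binarize_labels(yte, exercise_ids)
    proba = binary.predict_proba(Xte)
    pos_col = int(np.where(binary.classes_ == 1)[0][0])
    m_bin = evaluate(ybin, binary.predict(Xte), "binary",
                     proba_positive=proba[:, pos_col])

    multi = FcnClassifier.load(models / "multiclass")
    ex_mask = ybin == 1
    m_multi = evaluate(yte[ex_mask], multi.predict(Xte[ex_mask]),
                       "multiclass", labels=multi.classes_)

    reports = out / "reports"
    reports.mkdir(exist_ok=True)
    payload = {"binary": m_bin.to_dict(), "multiclass": m_multi.to_dict()}
    (reports / "metrics.json").write_text(json.dumps(payload, indent=2))
    _update_manifest(cfg, "evaluate", _time.time() - t0, {
        "binary_accuracy": m_bin.accuracy,
        "multiclass_macro_f1": m_multi.macro_f1})
    return payload


# ---------------------------------------------------------------------------
# track
# ---------------------------------------------------------------------------

def run_track(cfg: RunConfig) -> Path:
    """Detect exercise in recordings and roll up daily participation."""
    t0 = _time.time()
    out = _out(cfg)
    recdir = _require(out / "recordings", "track", "simulate")
    models = out / "models"
    _require(models / "binary.npz", "track", "train")
    sc = np.load(_require(out / "prep" / "scaler.npz", "track", "prep"))
    scaler = ChannelScaler(mean=sc["mean"], std=sc["std"])
    binary = FcnClassifier.load(models / "binary")
    pcfg = cfg.participation
    wcfg = cfg.windows

    sessions, _ = _load_recordings(recdir)
    bouts = []
    for rec, _spans in sessions:
        series = predict_recording(binary, rec, scaler,
                                   window_s=wcfg["window_s"],
                                   stride_s=wcfg["infer_stride_s"])
        bouts.extend(extract_bouts(series, pcfg["smoothing_width"],
                                   pcfg["min_bout_s"]))
    daily = daily_rollup(bouts, pcfg["expectation_min"],
                         pcfg["session_gap_min"])
    track = out / "track"
    track.mkdir(exist_ok=True)
    daily.to_csv(track / "daily_participation.csv", index=False)

    if len(daily):
        starts = {p: daily[daily.patient_id == p].date.min()
                  for p in daily.patient_id.unique()}
        n_weeks = 12
        wk = weekly_minutes(daily, starts, n_weeks, "home")
        wk.to_csv(track / "weekly_summary.csv", index=False)
        weekday, hour = temporal_patterns(bouts, pcfg["session_gap_min"])
        weekday.to_csv(track / "patterns_weekday.csv", header=True)
        hour.to_csv(track / "patterns_hour.csv", header=True)
    _update_manifest(cfg, "track", _time.time() - t0,
                     {"n_bouts": len(bouts), "n_days": len(daily)})
    return track


# ---------------------------------------------------------------------------
# analyze
# ---------------------------------------------------------------------------

def ground_truth_daily(cohort_tables: dict, expectation_min: float = 20.0
                       ) -> pd.DataFrame:
    """Build the daily participation table from scheduled ground truth."""
    gt = cohort_tables["ground_truth_participation"]
    piv = gt.pivot_table(index=["patient_id", "date"], columns="setting",
                         values="minutes", aggfunc="sum", fill_value=0.0)
    piv = piv.reset_index()
    for col in ("home", "clinic"):
        if col not in piv.columns:
            piv[col] = 0.0
    sess_counts = (gt.groupby(["patient_id", "date"]).size()
                   .rename("session_count").reset_index())
    df = piv.merge(sess_counts, on=["patient_id", "date"])
    df = df.rename(columns={"home": "minutes_home",
                            "clinic": "minutes_clinic"})
    total = df.minutes_home + df.minutes_clinic
    df["participation_ratio"] = np.minimum(total / expectation_min, 1.0)
    return df[["patient_id", "date", "minutes_home", "minutes_clinic",
               "session_count", "participation_ratio"]]


def run_analyze(cfg: RunConfig) -> dict:
    """Dose-response, MCID thresholds, participation patterns, predictors."""
    t0 = _time.time()
    out = _out(cfg)
    cohort_dir = _require(out / "cohort", "analyze", "simulate")
    tables = ptio.read_cohort_csvs(cohort_dir)
    pcfg = cfg.participation
    acfg = cfg.analysis

    if acfg.get("source", "ground_truth") == "detected":
        path = _require(out / "track" / "daily_participation.csv",
                        "analyze", "track")
        daily = pd.read_csv(path)
        daily["date"] = pd.to_datetime(daily["date"]).dt.date
    else:
        daily = ground_truth_daily(tables, pcfg["expectation_min"])

    assigned = tables["assigned_days"]
    outcomes = tables["outcomes"]
    baselines = tables["baselines"]
    start = assigned.date.min()
    starts = {p: start for p in baselines.patient_id}
    weeks = int(np.ceil(((assigned.date.max() - start).days + 1) / 7))

    analysis = out / "analysis"
    analysis.mkdir(exist_ok=True)
    report_lines = []

    # participation description
    frac = adherent_days_fraction(
        daily, assigned[assigned.home_assigned][["patient_id", "date"]])
    report_lines.append(
        f"Participation on {frac * 100:.0f}% of home-assigned days.")
    wk_home = weekly_minutes(daily, starts, weeks, "home")
    phase = None
    if weeks >= 12:
        phase = phase_comparison(wk_home)
        report_lines.append(
            f"Home minutes/week: median {phase.median_early:.0f} (weeks 1-4) -> "
            f"{phase.median_late:.0f} (weeks 9-12), paired t={phase.t_statistic:.2f}, "
            f"p={phase.p_value:.3f} (n={phase.n}).")
    else:
        report_lines.append(
            f"Treatment period {weeks} wk: too short for the early/late "
            "phase comparison (needs 12 weeks).")

    # dose response per instrument and timepoint
    wide = outcomes.pivot_table(index="patient_id", columns="week")
    rows = []
    fits = {}
    for instrument, col in (("dash", "dash"), ("nprs", "nprs_average")):
        base_scores = wide[(col, 0)]
        for w in acfg["timepoints"]:
            if (col, w) not in wide.columns:
                continue
            part = cumulative_participation(daily, assigned, w, starts)
            imp = pd.Series({p: improvement(base_scores[p], wide[(col, w)][p])
                             for p in wide.index})
            joined = pd.concat([part, imp], axis=1, keys=["x", "y"]).dropna()
            fit = dose_response(joined.x, joined.y, w)
            fits[(instrument, w)] = fit
            rows.append((instrument, w, fit.n, fit.slope, fit.intercept,
                         fit.pearson_r, fit.p_value))
            report_lines.append(
                f"{instrument.upper()} at {w} wk: n={fit.n}, slope={fit.slope:.3f}, "
                f"R={fit.pearson_r:.2f}, p={fit.p_value:.3f}")
    pd.DataFrame(rows, columns=["instrument", "week", "n", "slope",
                                "intercept", "pearson_r", "p_value"]
                 ).to_csv(analysis / "dose_response.csv", index=False)

    # MCID thresholds from the final-timepoint slopes
    last_w = max(w for (_, w) in fits)
    thresholds = {}
    dash_fit = fits.get(("dash", last_w))
    if dash_fit and dash_fit.slope > 0:
        thresholds["dash"] = mcid_threshold(DASH_MCID, dash_fit.slope)
        report_lines.append(
            f"DASH MCID ({DASH_MCID}) reached at +{thresholds['dash']}% "
            f"participation (slope {dash_fit.slope:.3f}).")
    nprs_fit = fits.get(("nprs", last_w))
    if nprs_fit and nprs_fit.slope > 0:
        lo = mcid_threshold(NPRS_MCID_RANGE[0], nprs_fit.slope)
        hi = mcid_threshold(NPRS_MCID_RANGE[1], nprs_fit.slope)
        thresholds["nprs"] = [lo, hi]
        report_lines.append(
            f"NPRS MCID ({NPRS_MCID_RANGE[0]}-{NPRS_MCID_RANGE[1]}) reached "
            f"at +{lo}% to +{hi}% participation (slope {nprs_fit.slope:.3f}).")

    # improvement proportions at the final timepoint
    for instrument, col, mcid in (("dash", "dash", DASH_MCID),
                                  ("nprs", "nprs_average", NPRS_MCID_RANGE[0])):
        if (col, last_w) in wide.columns:
            ch = [improvement(wide[(col, 0)][p], wide[(col, last_w)][p])
                  for p in wide.index]
            ch = [c for c in ch if not np.isnan(c)]
            if ch:
                pi, pm = proportions(ch, mcid)
                report_lines.append(
                    f"{instrument.upper()} at {last_w} wk: {pi}% improved, "
                    f"{pm}% beyond MCID {mcid}.")

    # univariable adherence predictors at 4 weeks
    part4 = cumulative_participation(daily, assigned, 4, starts)
    preds = predictor_analysis(baselines, part4)
    pd.DataFrame([{
        "variable": r.variable, "test": r.test, "statistic": r.statistic,
        "p_value": r.p_value,
        "group1_mean": r.group_means[0] if r.group_means else np.nan,
        "group1_sd": r.group_means[1] if r.group_means else np.nan,
        "group0_mean": r.group_means[2] if r.group_means else np.nan,
        "group0_sd": r.group_means[3] if r.group_means else np.nan,
    } for r in preds]).to_csv(analysis / "predictors.csv", index=False)

    (analysis / "report.txt").write_text("\n".join(report_lines) + "\n")
    _update_manifest(cfg, "analyze", _time.time() - t0,
                     {"adherent_day_fraction": frac})
    return {"fits": fits, "thresholds": thresholds,
            "adherent_day_fraction": frac, "phase": phase,
            "predictors": preds, "report": report_lines}


def run_pipeline(cfg: RunConfig, stages=STAGES, force: bool = False) -> dict:
    """Run the requested stages in canonical order; returns stage outputs."""
    order = [s for s in STAGES if s in stages]
    unknown = set(stages) - set(STAGES) - {"simulate"}
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    results = {}
    if "simulate" in stages:
        results["simulate"] = run_simulate(cfg, force=force)
    runners = {"prep": run_prep, "train": run_train, "evaluate": run_evaluate,
               "track": run_track, "analyze": run_analyze}
    for s in order:
        logger.info("running stage %s", s)
        results[s] = runners[s](cfg)
    return results
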