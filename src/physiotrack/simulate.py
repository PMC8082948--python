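"""Synthetic smartwatch data with known ground truth.

Emulates the data a wrist-worn inertial tracker produces during a 12-week
shoulder rehabilitation program, at three levels:

* **signal level** — quasi-periodic 9-channel inertial traces for exercise
  motion classes versus flat/irregular traces for activities of daily
  living (ADL), so an activity classifier has the oscillatory-vs-flat
  contrast real exercise tracking exploits;
* **session level** — supervised sessions as exercise bouts separated by
  inter-exercise rest, with sample-accurate label spans;
* **cohort level** — patient baselines, per-day home/clinic session
  schedules with a declining home-participation probability, bimodal
  time-of-day usage, and pain/disability outcome trajectories carrying a
  planted linear dose-response on cumulative participation.

Every output is a pure function of (config, seed); the ground-truth
participation table records the exact scheduled exercise minutes so
downstream estimators can be checked against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta

import numpy as np
import pandas as pd

from .records import GRAVITY_MS2, N_CHANNELS, ImuRecording, LabelSpan

__all__ = [
    "MotionClassSpec",
    "CohortSimConfig",
    "SyntheticCohort",
    "default_motion_classes",
    "gen_signal",
    "gen_session",
    "gen_cohort",
    "iter_session_recordings",
]


# ---------------------------------------------------------------------------
# motion classes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotionClassSpec:
    """Parameters of one synthetic motion class.

    ``fundamental_hz`` is the dominant oscillation frequency; exercise
    classes use slow repetitions (0.2-1.0 Hz), walking sits near 2 Hz and
    sedentary ADL classes have (near-)zero oscillation amplitude.
    ``axis_weights`` are per-channel amplitude loadings in the fixed
    channel order (accel xyz, gyro xyz, mag xyz); ``harmonic_ratio`` is
    the relative amplitude of the second harmonic. When ``gravity`` is
    set, a constant ~9.81 m/s^2 projection is mixed into the
    accelerometer channels.
    """

    class_id: int
    kind: str  # "exercise" | "adl"
    fundamental_hz: float
    axis_weights: tuple[float, ...]
    harmonic_ratio: float = 0.3
    noise_sd: float = 0.3
    gravity: bool = True
    drift_amp: float = 0.0  # slow orientation drift amplitude (exercise realism)
    name: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.fundamental_hz <= 5.0):
            raise ValueError("fundamental_hz must be in (0, 5]")
        if len(self.axis_weights) != N_CHANNELS:
            raise ValueError(f"axis_weights must have {N_CHANNELS} entries")
        w = np.asarray(self.axis_weights, dtype=float)
        if not np.isfinite(w).all():
            raise ValueError("axis_weights must be finite")
        if self.kind == "exercise" and not np.any(w != 0):
            raise ValueError("exercise classes need a nonzero axis weight")
        if self.kind not in ("exercise", "adl"):
            raise ValueError("kind must be 'exercise' or 'adl'")


# ADL class ids live above 100 so they never collide with exercise ids.
ADL_REST, ADL_WALK, ADL_COMPUTER, ADL_HOUSEHOLD = 101, 102, 103, 104


def default_motion_classes() -> dict[int, MotionClassSpec]:
    """Default protocol: 7 exercise principal-motion classes + 4 ADL classes.

    The exercise classes stand in for a multi-exercise rotator cuff
    protocol collapsed onto principal motions (flexion, abduction,
    rotations, rows...); each gets a distinct repetition frequency and
    channel loading so they are mutually separable. ADL classes cover
    rest, walking, desk work and irregular household activity.
    """
    ex = {}
    # (fundamental Hz, accel loading pattern, gyro loading pattern)
    params = [
        (0.30, (0.8, 0.2, 0.1), (1.5, 0.3, 0.2)),   # forward flexion
        (0.40, (0.2, 0.9, 0.1), (0.3, 1.6, 0.2)),   # abduction
        (0.50, (0.1, 0.2, 0.8), (0.2, 0.3, 1.7)),   # external rotation
        (0.60, (0.7, 0.7, 0.1), (1.2, 1.2, 0.2)),   # internal rotation
        (0.70, (0.3, 0.1, 0.9), (0.4, 1.5, 1.0)),   # scaption
        (0.85, (0.9, 0.4, 0.4), (1.7, 0.5, 0.6)),   # rows
        (1.00, (0.5, 0.8, 0.6), (0.8, 1.0, 1.4)),   # pendulum
    ]
    names = ["flexion", "abduction", "external_rotation", "internal_rotation",
             "scaption", "rows", "pendulum"]
    for i, ((f, acc, gyr), name) in enumerate(zip(params, names), start=1):
        mag = (0.15, 0.15, 0.15)
        ex[i] = MotionClassSpec(
            class_id=i, kind="exercise", fundamental_hz=f,
            axis_weights=(*[2.0 * a for a in acc], *gyr, *mag),
            harmonic_ratio=0.3, noise_sd=0.35, drift_amp=0.15, name=name,
        )
    adl = {
        ADL_REST: MotionClassSpec(
            class_id=ADL_REST, kind="adl", fundamental_hz=1.0,
            axis_weights=(0.0,) * 9, noise_sd=0.05, name="rest"),
        ADL_WALK: MotionClassSpec(
            class_id=ADL_WALK, kind="adl", fundamental_hz=2.0,
            axis_weights=(0.4, 0.3, 2.2, 0.25, 0.2, 0.3, 0.1, 0.1, 0.1),
            harmonic_ratio=0.5, noise_sd=0.5, name="walking"),
        ADL_COMPUTER: MotionClassSpec(
            class_id=ADL_COMPUTER, kind="adl", fundamental_hz=1.0,
            axis_weights=(0.0,) * 9, noise_sd=0.18, name="computer_work"),
        ADL_HOUSEHOLD: MotionClassSpec(
            class_id=ADL_HOUSEHOLD, kind="adl", fundamental_hz=0.9,
            axis_weights=(0.25, 0.25, 0.25, 0.35, 0.35, 0.35, 0.1, 0.1, 0.1),
            harmonic_ratio=0.2, noise_sd=1.3, name="household"),
    }
    return {**ex, **adl}


# ---------------------------------------------------------------------------
# signal generation
# ---------------------------------------------------------------------------

def gen_signal(
    spec: MotionClassSpec,
    duration_s: float,
    sample_rate_hz: float = 50.0,
    seed: int = 0,
) -> np.ndarray:
    """Generate one (T, 9) inertial segment for a motion class.

    Exercise classes produce a fundamental sinusoid plus one harmonic with
    per-channel loadings, optional slow orientation drift and white noise;
    gravity is projected onto the accelerometer channels. A zero-weight,
    zero-noise spec yields the constant gravity vector on the
    accelerometer and zeros elsewhere.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if sample_rate_hz <= 0:
        raise ValueError("sample_rate_hz must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz

    w = np.asarray(spec.axis_weights, dtype=float)
    phase = rng.uniform(0, 2 * np.pi, size=N_CHANNELS)
    phase2 = rng.uniform(0, 2 * np.pi, size=N_CHANNELS)
    base = np.sin(2 * np.pi * spec.fundamental_hz * t[:, None] + phase[None, :])
    harm = np.sin(2 * np.pi * 2 * spec.fundamental_hz * t[:, None] + phase2[None, :])
    x = w[None, :] * (base + spec.harmonic_ratio * harm)

    if spec.drift_amp > 0:
        # slow wandering of the mean, mimicking posture changes between reps
        drift_hz = rng.uniform(0.02, 0.05)
        dphase = rng.uniform(0, 2 * np.pi, size=N_CHANNELS)
        x += spec.drift_amp * np.sin(2 * np.pi * drift_hz * t[:, None] + dphase)

    if spec.gravity:
        # fixed wrist orientation per segment: unit vector onto accel axes
        g = rng.normal(size=3)
        g /= np.linalg.norm(g)
        x[:, :3] += GRAVITY_MS2 * g[None, :]

    if spec.noise_sd > 0:
        x += rng.normal(0.0, spec.noise_sd, size=x.shape)
    return x


def gen_adl_recording(
    spec: MotionClassSpec,
    duration_s: float,
    sample_rate_hz: float = 50.0,
    seed: int = 0,
    segment_s: float = 60.0,
) -> np.ndarray:
    """Generate a long daily-living trace as concatenated short segments.

    Hours of real background wear cover many wrist orientations and
    activity micro-variations; a single :func:`gen_signal` call has one
    fixed gravity orientation and phase. Concatenating ~minute-long
    segments, each with its own seed, restores that within-recording
    variety so classifiers cannot key on a recording-constant offset.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    blocks, remaining = [], duration_s
    while remaining > 1e-9:
        d = min(segment_s, remaining)
        blocks.append(gen_signal(spec, d, sample_rate_hz,
                                 seed=int(rng.integers(2**31))))
        remaining -= d
    return np.concatenate(blocks, axis=0)


def gen_session(
    exercise_plan: list[tuple[int, float]],
    rest_gap_s: float = 30.0,
    seed: int = 0,
    *,
    classes: dict[int, MotionClassSpec] | None = None,
    sample_rate_hz: float = 50.0,
    patient_id: str = "p0",
    session_id: str = "s0",
    setting: str = "home",
    start_datetime: datetime = datetime(2021, 1, 4, 10, 0),
) -> tuple[ImuRecording, list[LabelSpan]]:
    """Generate one supervised session: exercise bouts joined by rest gaps.

    ``exercise_plan`` is an ordered list of ``(class_id, duration_s)``.
    Gaps are inserted *between* bouts only. The returned label spans tile
    the exercise bouts exactly, sample-accurately.
    """
    if not exercise_plan:
        raise ValueError("exercise_plan must not be empty")
    classes = classes if classes is not None else default_motion_classes()
    rest_spec = classes.get(ADL_REST) or MotionClassSpec(
        class_id=ADL_REST, kind="adl", fundamental_hz=1.0,
        axis_weights=(0.0,) * 9, noise_sd=0.05, name="rest")
    rng = np.random.default_rng(seed)

    blocks: list[np.ndarray] = []
    spans: list[LabelSpan] = []
    cursor = 0  # in samples, so span times are sample-accurate
    for i, (class_id, dur_s) in enumerate(exercise_plan):
        if class_id not in classes:
            raise KeyError(f"unknown motion class id {class_id}")
        if i > 0 and rest_gap_s > 0:
            gap = gen_signal(rest_spec, rest_gap_s, sample_rate_hz,
                             seed=int(rng.integers(2**31)))
            blocks.append(gap)
            cursor += gap.shape[0]
        seg = gen_signal(classes[class_id], dur_s, sample_rate_hz,
                         seed=int(rng.integers(2**31)))
        start = cursor / sample_rate_hz
        cursor += seg.shape[0]
        end = cursor / sample_rate_hz
        blocks.append(seg)
        n_reps = max(1, int(round(dur_s * classes[class_id].fundamental_hz)))
        spans.append(LabelSpan(start, end, class_id, repetitions=n_reps))

    rec = ImuRecording(
        patient_id=patient_id, session_id=session_id, setting=setting,
        start_datetime=start_datetime, sample_rate_hz=sample_rate_hz,
        samples=np.concatenate(blocks, axis=0),
    )
    return rec, spans


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSimConfig:
    """Study conditions for a synthetic rehabilitation cohort.

    The defaults emulate the observed cohort: ~20 minutes/day expected
    home exercise, one weekly ~10-minute supervised clinic session, home
    participation probability declining multiplicatively per week,
    bimodal session start times (morning/evening), and outcome
    improvement linear in cumulative participation percent with planted
    slopes of 0.37 disability points and 0.056 pain points per
    participation percentage point.
    """

    n_patients: int = 42
    weeks: int = 12
    expectation_min_per_day: float = 20.0
    true_slope_dash: float = 0.37
    true_slope_pain: float = 0.056
    #: logit-scale weights of standardized baseline covariates on the
    #: latent home-adherence propensity
    adherence_coefficients: dict = field(default_factory=lambda: {
        "peq": 0.55, "pseq": 0.35, "hads_anxiety": -0.35, "income": 0.35,
    })
    base_home_logit: float = 0.4       # ~60% home-session probability at week 0
    decline_rate: float = 0.87         # weekly multiplicative decay of home p
    #: two wrapped-normal components over hour-of-day: (mean_h, sd_h, weight)
    timeofday_mixture: tuple = ((10.0, 1.5, 0.45), (21.0, 1.5, 0.55))
    #: log-normal home session length: median minutes and log-scale sd
    session_minutes_median: float = 12.0
    session_minutes_logsd: float = 0.35
    clinic_minutes_mean: float = 10.0
    clinic_minutes_sd: float = 2.0
    outcome_noise_sd: float = 6.0      # residual SD of DASH improvement
    start_date: date = date(2021, 1, 4)  # a Monday
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.weeks < 1:
            raise ValueError("weeks must be >= 1")
        if not (0.0 < self.decline_rate <= 1.0):
            raise ValueError("decline_rate must be in (0, 1]")
        wsum = sum(c[2] for c in self.timeofday_mixture)
        if abs(wsum - 1.0) > 1e-9:
            raise ValueError("time-of-day mixture weights must sum to 1")
        if self.expectation_min_per_day <= 0:
            raise ValueError("expectation_min_per_day must be positive")


@dataclass
class SyntheticCohort:
    """Bundle of simulated cohort tables (all plain pandas DataFrames).

    ``baselines``: one row per patient with covariates.
    ``sessions``: one row per scheduled session (patient, date, setting,
    start time, minutes, per-session RNG seed).
    ``ground_truth``: exact scheduled exercise minutes per patient-day and
    setting.
    ``outcomes``: long-format instrument scores at weeks 0/4/8/12.
    ``assigned``: per patient-day flag of home-exercise assignment.
    """

    config: CohortSimConfig
    baselines: pd.DataFrame
    sessions: pd.DataFrame
    ground_truth: pd.DataFrame
    outcomes: pd.DataFrame
    assigned: pd.DataFrame
    #: per-patient true cumulative participation percent at each timepoint
    true_participation: pd.DataFrame


def _sample_timeofday(rng: np.random.Generator, mixture) -> float:
    means = np.array([c[0] for c in mixture])
    sds = np.array([c[1] for c in mixture])
    weights = np.array([c[2] for c in mixture])
    k = rng.choice(len(mixture), p=weights / weights.sum())
    return float(np.mod(rng.normal(means[k], sds[k]), 24.0))


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    """Rejection-sampled truncated normal (ranges are wide; cheap)."""
    x = rng.normal(mean, sd, size=size)
    bad = (x < lo) | (x > hi)
    while np.any(bad):
        x = np.where(bad, rng.normal(mean, sd, size=size), x)
        bad = (x < lo) | (x > hi)
    return x


def gen_cohort(config: CohortSimConfig) -> SyntheticCohort:
    """Simulate a full cohort: baselines, schedules, outcomes, ground truth.

    Home-session indicators are Bernoulli with probability
    ``sigmoid(base_logit + beta . z_i) * decline_rate**week`` where ``z_i``
    are the patient's standardized covariates; session start times follow
    the bimodal time-of-day mixture; one weekly supervised clinic session
    contributes ~10 minutes. Outcome improvement at week *w* equals
    ``true_slope * cumulative_participation_percent(w) + noise``.

    Recordings are not materialized here (a full cohort at 50 Hz is
    gigabytes); use :func:`iter_session_recordings` to realize any
    session's trace and label spans on demand from its stored seed.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients

    # --- baselines (distributions match the study cohort's summary table)
    pid = [f"P{i:03d}" for i in range(n)]
    base = pd.DataFrame({
        "patient_id": pid,
        "age": np.round(_truncnorm(rng, 45, 13, 18, 85, n)),
        "sex_male": (rng.random(n) < 0.36).astype(int),
        "bmi": _truncnorm(rng, 26, 4, 16, 45, n),
        "baseline_activity_hr_wk": _truncnorm(rng, 3.6, 4.4, 0, 25, n),
        "working": (rng.random(n) < 0.45).astype(int),
        "compensation_claim": (rng.random(n) < 0.21).astype(int),
        # ordinal income bands 1..5, median band 3 (40-60k)
        "income": rng.choice([1, 2, 3, 4, 5], size=n,
                             p=[0.15, 0.2, 0.3, 0.2, 0.15]),
        "education_university": (rng.random(n) < 0.50).astype(int),
        "essi": np.round(_truncnorm(rng, 26, 5, 8, 34, n)),
        "pseq": np.round(_truncnorm(rng, 8.0, 3.2, 0, 12, n)),
        "peq": np.round(_truncnorm(rng, 18, 4, 4, 23, n)),
        "hads_anxiety": np.round(_truncnorm(rng, 7.0, 5.5, 0, 21, n)),
        "hads_depression": np.round(_truncnorm(rng, 5.5, 3.5, 0, 21, n)),
        "dash_baseline": _truncnorm(rng, 44, 21, 10, 95, n),
        "nprs_baseline": _truncnorm(rng, 5.2, 1.9, 0.8, 9.2, n),
    })

    # --- latent home-adherence propensity
    logit = np.full(n, cfg.base_home_logit, dtype=float)
    for var, beta in cfg.adherence_coefficients.items():
        v = base[var].to_numpy(dtype=float)
        sd = v.std(ddof=0)
        z = (v - v.mean()) / sd if sd > 0 else np.zeros(n)
        logit += beta * z
    p_home0 = 1.0 / (1.0 + np.exp(-logit))

    # --- day-by-day schedule
    n_days = cfg.weeks * 7
    clinic_weekday = rng.integers(0, 5, size=n)  # each patient's clinic day
    sess_rows, assigned_rows = [], []
    for i in range(n):
        for d in range(n_days):
            day = cfg.start_date + timedelta(days=d)
            week = d // 7
            is_clinic = day.weekday() == clinic_weekday[i]
            assigned_rows.append((pid[i], day, not is_clinic))
            if is_clinic:
                minutes = float(np.clip(
                    rng.normal(cfg.clinic_minutes_mean, cfg.clinic_minutes_sd),
                    3.0, 25.0))
                start_h = float(np.clip(rng.normal(14.0, 2.0), 8.0, 18.0))
                sess_rows.append((pid[i], day, "clinic", start_h,
                                  round(minutes * 60) / 60,
                                  int(rng.integers(2**31))))
            else:
                p = p_home0[i] * cfg.decline_rate ** week
                if rng.random() < p:
                    minutes = float(np.clip(
                        np.exp(rng.normal(np.log(cfg.session_minutes_median),
                                          cfg.session_minutes_logsd)),
                        3.0, 40.0))
                    start_h = _sample_timeofday(rng, cfg.timeofday_mixture)
                    sess_rows.append((pid[i], day, "home", start_h,
                                      round(minutes * 60) / 60,
                                      int(rng.integers(2**31))))

    sessions = pd.DataFrame(
        sess_rows, columns=["patient_id", "date", "setting", "start_hour",
                            "minutes", "session_seed"])
    sessions["session_id"] = [
        f"{p}_{d.isoformat()}_{s}" for p, d, s in
        zip(sessions.patient_id, sessions.date, sessions.setting)]
    assigned = pd.DataFrame(assigned_rows,
                            columns=["patient_id", "date", "home_assigned"])

    ground_truth = (sessions
                    .groupby(["patient_id", "date", "setting"], as_index=False)
                    ["minutes"].sum())

    # --- true cumulative participation percent per timepoint
    daily = (sessions.groupby(["patient_id", "date"], as_index=False)
             ["minutes"].sum())
    cal = assigned.merge(daily, on=["patient_id", "date"], how="left")
    cal["minutes"] = cal["minutes"].fillna(0.0)
    cal["ratio"] = np.minimum(cal["minutes"] / cfg.expectation_min_per_day, 1.0)
    cal["day_index"] = (pd.to_datetime(cal["date"])
                        - pd.Timestamp(cfg.start_date)).dt.days

    timepoints = [w for w in (4, 8, 12) if w <= cfg.weeks]
    part_rows = []
    for p in pid:
        sub = cal[cal.patient_id == p]
        for w in timepoints:
            mask = sub.day_index < w * 7
            # participation denominator: home-assigned days only
            dd = sub[mask & sub.home_assigned]
            part = 100.0 * dd["ratio"].mean() if len(dd) else 0.0
            part_rows.append((p, w, part))
    true_part = pd.DataFrame(part_rows,
                             columns=["patient_id", "week", "participation_pct"])

    # --- outcomes with planted linear dose response
    def _nprs_items(v: float, rng) -> tuple[float, float, float]:
        # three survey items (rest, activity, past-week average) whose
        # arithmetic mean equals v exactly; v kept off the scale edges so
        # the spread stays inside [0, 10]
        v = float(np.clip(v, 0.9, 9.1))
        d1, d2 = rng.uniform(-0.4, 0.4, size=2)
        return v + d1, v + d2, v - d1 - d2

    out_rows = []
    for i, p in enumerate(pid):
        dash0 = float(base.loc[i, "dash_baseline"])
        nprs0 = float(base.loc[i, "nprs_baseline"])
        r0, a0, av0 = _nprs_items(nprs0, rng)
        out_rows.append((p, 0, dash0, r0, a0, av0))
        for w in timepoints:
            part = float(true_part[(true_part.patient_id == p)
                                   & (true_part.week == w)]
                         ["participation_pct"].iloc[0])
            noise_d = rng.normal(0, cfg.outcome_noise_sd)
            noise_p = rng.normal(0, cfg.outcome_noise_sd * cfg.true_slope_pain
                                 / max(cfg.true_slope_dash, 1e-12))
            # DASH stays exactly linear (may marginally exit [0,100] under
            # extreme configs; kept unclipped so the planted slope is exact)
            dash_w = dash0 - (cfg.true_slope_dash * part + noise_d)
            v_w = nprs0 - (cfg.true_slope_pain * part + noise_p)
            r, a, av = _nprs_items(v_w, rng)
            out_rows.append((p, w, dash_w, r, a, av))
    outcomes = pd.DataFrame(
        out_rows, columns=["patient_id", "week", "dash",
                           "nprs_rest", "nprs_activity", "nprs_average"])

    return SyntheticCohort(cfg, base, sessions, ground_truth, outcomes,
                           assigned, true_part)


MIN_BOUT_PLAN_S = 90  # every planned exercise bout lasts at least this long


def _session_plan(minutes: float, rng: np.random.Generator,
                  exercise_ids: list[int]) -> list[tuple[int, float]]:
    """Split a session's exercise minutes into whole-second bouts.

    Bout durations are integer seconds summing exactly to the scheduled
    total (so the ground-truth table and generated label spans agree) and
    each bout lasts at least :data:`MIN_BOUT_PLAN_S` seconds, matching
    how patients do one exercise for a couple of minutes before moving on.
    """
    total_s = int(round(minutes * 60))
    n_bouts = max(1, min(len(exercise_ids), total_s // MIN_BOUT_PLAN_S))
    extra = total_s - MIN_BOUT_PLAN_S * n_bouts
    if n_bouts > 1 and extra > 0:
        w = rng.dirichlet(np.ones(n_bouts))
        add = np.floor(w * extra).astype(int)
        add[np.argmax(w)] += extra - add.sum()   # exact total
    else:
        add = np.array([max(extra, 0)] + [0] * (n_bouts - 1))
    durs = MIN_BOUT_PLAN_S + add if total_s >= MIN_BOUT_PLAN_S else np.array([total_s])
    ids = (rng.choice(exercise_ids, size=n_bouts,
                      replace=len(exercise_ids) < n_bouts).tolist()
           if n_bouts > 1 else [int(rng.choice(exercise_ids))])
    return [(int(c), float(d)) for c, d in zip(ids, np.atleast_1d(durs))]


def iter_session_recordings(
    cohort: SyntheticCohort,
    patient_ids: list[str] | None = None,
    classes: dict[int, MotionClassSpec] | None = None,
    sample_rate_hz: float = 50.0,
):
    """Materialize recordings for scheduled sessions, one at a time.

    Yields ``(ImuRecording, [LabelSpan])`` for each session row, using the
    per-session seed stored in the schedule, so any subset can be realized
    reproducibly without holding a multi-gigabyte cohort in memory. The
    summed span durations of each recording equal the session's scheduled
    minutes exactly.
    """
    classes = classes if classes is not None else default_motion_classes()
    exercise_ids = [c.class_id for c in classes.values() if c.kind == "exercise"]
    sessions = cohort.sessions
    if patient_ids is not None:
        sessions = sessions[sessions.patient_id.isin(patient_ids)]
    for row in sessions.itertuples(index=False):
        rng = np.random.default_rng(row.session_seed)
        plan = _session_plan(row.minutes, rng, exercise_ids)
        h = int(row.start_hour)
        m = int((row.start_hour - h) * 60)
        start_dt = datetime.combine(row.date, time(h, m))
        rec, spans = gen_session(
            plan, rest_gap_s=float(rng.uniform(20, 40)),
            seed=int(rng.integers(2**31)), classes=classes,
            sample_rate_hz=sample_rate_hz, patient_id=row.patient_id,
            session_id=row.session_id, setting=row.setting,
            start_datetime=start_dt,
        )
        yield rec, spans
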