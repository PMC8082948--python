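# Methods

This note documents the models, defaults and numerical choices behind
physiotrack: what the synthetic generator emulates, how the classifier
and the participation statistics are defined, and what the package's
passing tests do and do not establish about real data.

## Synthetic inertial signals

Each motion class is a 9-channel signal model

```
x_c(t) = w_c [ sin(2π f t + φ_c) + h · sin(4π f t + ψ_c) ] + drift + g_c + ε
```

with fundamental frequency `f`, per-channel amplitude loadings `w`
(accelerometer m/s², gyroscope rad/s, magnetometer µT, in the fixed
channel order ax..mz), second-harmonic ratio `h`, optional slow
orientation drift (a 0.02–0.05 Hz sinusoid), a constant gravity
projection `g` of 9.81 m/s² onto the accelerometer axes (random unit
orientation per segment), and white noise `ε`. Phases are drawn per
segment from the seed, so every trace is a pure function of
(spec, duration, rate, seed).

The default protocol has **7 exercise classes** (0.30–1.00 Hz, distinct
channel loadings standing in for flexion, abduction, rotations, rows,
scaption, pendulum) and **4 daily-living classes**: rest and computer
work (zero oscillation amplitude — gravity plus noise), walking
(~2 Hz, vertical-accelerometer dominant) and household activity
(broadband, high noise). This reproduces the oscillatory-vs-flat
contrast an exercise detector exploits while keeping the exercise
classes mutually separable mainly by frequency and loading. It is
deliberately *not* a biomechanical model: no subject-specific
kinematics, no fatigue, no sensor dropout.

Sessions concatenate exercise bouts with rest gaps between them; label
spans tile the bouts sample-accurately, so summed span durations equal
planned exercise time exactly. Long daily-living recordings are built
from ~1-minute segments, each with its own orientation and phases,
because hours of real background wear cover many wrist poses; without
this, a classifier can key on the recording-constant gravity offset and
fail on a held-out recording's unseen orientation (we observed exactly
that failure mode before switching).

## Synthetic cohorts

`CohortSimConfig` encodes the study conditions; all defaults were fixed
from the emulated study's reported conditions before the acceptance
suite was run, and are not tuned per test.

- **Baselines** (n patients): age ~ N(45, 13), BMI ~ N(26, 4), activity
  hours ~ N(3.6, 4.4), expectation score PEQ ~ N(18, 4), self-efficacy
  PSEQ-2 ~ N(8, 3.2), anxiety HADS-A ~ N(7, 5.5), depression ~ N(5.5,
  3.5), social support ESSI ~ N(26, 5), ordinal income (5 bands,
  median band 3), binary sex/work/compensation/education — all
  truncated to plausible instrument ranges.
- **Home adherence**: each non-clinic day is an assigned home-exercise
  day; a session occurs with probability
  `sigmoid(0.4 + β·z_i) · decline^week`, where `z_i` are the patient's
  standardized covariates with logit weights β = (PEQ 0.55, PSEQ 0.35,
  HADS-A −0.35, income 0.35) and `decline = 0.87` per week. The decline
  and the base rate were calibrated once so that the cohort reproduces
  the reported weekly home-minute medians (≈38 min/week in weeks 1–4
  falling to ≈13 in weeks 9–12). One weekly supervised clinic session
  contributes ~10 detected minutes.
- **Session timing and length**: home-session start times follow a
  two-component wrapped-normal mixture over hour-of-day with modes
  10:00 and 21:00 (SD 1.5 h, weights 0.45/0.55); durations are
  log-normal with median 12 minutes (log-SD 0.35, clipped 3–40), with
  each session split into bouts of ≥90 s. The daily-duration
  distribution is a modeling convenience consistent with sessions of
  roughly 5–15 minutes; no empirical distributional form exists to
  copy.
- **Outcomes**: improvement at week w equals
  `slope × cumulative_participation%(w) + noise`, with planted slopes
  0.37 DASH points and 0.056 NPRS points per participation percent.
  `outcome_noise_sd = 6.0` was derived from
  `0.37 · sd(participation) · sqrt(1/r² − 1)` with r = 0.4, the
  moderate correlation regime the analysis targets. DASH follow-ups are
  left unclipped so the planted slope is exactly identifiable (they can
  marginally exit [0, 100] under extreme configurations); NPRS values
  are kept inside the instrument range by clipping, which mildly
  attenuates the recovered pain slope (~5% at the defaults) — the cost
  of respecting the 0–10 floor. The three NPRS items are generated with
  offsets that cancel, so their mean equals the intended composite
  exactly.
- **Ground truth**: the schedule stores exact per-session minutes and a
  per-session RNG seed; recordings are materialized lazily
  (`iter_session_recordings`) because a full cohort at 50 Hz is
  gigabytes, and the materialized label spans sum exactly to the
  scheduled minutes.

## Windowing, labels, splitting

Windows are 10 s; training uses a 5-s stride (50% overlap, standard for
activity recognition), inference a 10-s stride so each second of a
recording is counted exactly once when predictions become minutes. A
window takes the principal-motion class of the single span covering
strictly more than half of it; ties and sub-threshold coverage are
`unlabeled` and excluded from training; in daily-living recordings the
un-spanned time *is* the activity, so those windows take the
recording's class. The train/test split is temporal and per patient:
the chronologically last session of every patient is held out
(duplicate timestamps break ties by session id, with a warning;
single-session patients contribute only to test, logged). Channels are
z-scored with statistics computed on the training split only.

## The classifier

The architecture is the canonical time-series FCN: stacked blocks of
(temporal convolution, 'same' padding → batch normalization → ReLU),
global average pooling over time, linear softmax head; default blocks
(128, 8), (256, 5), (128, 3). The implementation is self-contained
NumPy (im2col convolutions, full backprop, Adam at lr 1e-3, batch 64)
because the package targets plain CPU environments; it is deliberately
minimal and single-threaded-deterministic given a seed.

Two choices matter numerically:

- **Input decimation.** The three-block stack's receptive field spans
  ~14 samples. At 50 Hz that is 0.28 s — far less than one repetition
  of a 0.2–1 Hz exercise, so frequency, the main discriminator between
  exercise classes, is invisible and held-out-session accuracy
  collapses for class pairs sharing loadings. Block-average decimation
  (`downsample`, benchmark default 8×, i.e. 6.25 Hz) brings a full
  period inside the receptive field and cuts training time ~6×. All
  signal content of interest is below the post-decimation Nyquist.
- **Early stopping** monitors validation *cross-entropy* on a
  patient-held-out fold (15% of groups), with patience 10, snapshotting
  weights *and* batch-norm running statistics together. Accuracy is too
  coarse a monitor: on a small fold it can peak by luck on a
  barely-trained net; and restoring weights without their matching
  normalization statistics silently corrupts inference.

The binary task (any exercise vs. daily living) and the multiclass task
(which exercise, trained and scored on exercise windows only) are
separate models over the same window stream.

## Participation

A **bout** is a maximal run of positive windows after median filtering
(width 3) of the non-overlapping prediction stream, kept if ≥60 s.
Bouts less than 30 minutes apart form one **session**. Daily minutes
are summed per calendar date and setting (home/clinic attribution comes
from recording metadata, matching a design where clinic sessions are
supervised); the participation ratio is capped at 1. A day counts as
participating if at least one bout survives. The assigned-day
denominator excludes clinic-visit days by default (patients are asked
to exercise on the other days); cumulative participation percent is 100
× the mean daily ratio over assigned days, the simplest aggregation
consistent with a capped daily ratio (the alternative, total minutes
over total expected minutes, is one config switch away). Weeks are
indexed from each patient's treatment start, not calendar weeks. The
time-of-day histogram assigns a session to its nearest hour, so the bin
labeled 10 means "sessions around 10:00".

With an oracle classifier (ground-truth labels as predictions), daily
minutes match the generator's schedule to within one 10-s window per
bout boundary — the quantization floor of window-level detection. The
≥90-s planned bouts guarantee no bout is lost to the 60-s minimum after
boundary quantization.

## Outcome statistics

Improvement is baseline − follow-up for both instruments (positive =
better, so a beneficial dose response has positive slope). Dose
response is OLS of improvement on cumulative participation percent with
Pearson r and its two-sided p; missing follow-ups are dropped per
timepoint (complete case). The MCID threshold is `mcid / slope`
rounded half-away-from-zero to integer percent (DASH MCID 10.83, NPRS
1–2.2); it is undefined for non-positive slopes. Predictor analysis is
univariable and unadjusted by design (exploratory): Pearson for
continuous, Spearman for ordinal, pooled-variance two-sample t with
group mean (SD) for binary variables; education enters dichotomized.

## Benchmark problem sizes

The seeded classifier benchmark uses 5 synthetic patients × 5 sessions
(one 60-s bout of each of the 7 exercise classes per session) plus 4
volunteer recordings of 360 s per daily-living class (last one per
class held out), giving ≈220 training windows per class under the
temporal split, and an FCN of (32, 8)/(64, 5)/(32, 3) with up to 30
epochs — sized so the whole benchmark trains in about a minute on one
CPU while exceeding 200 windows per class. Dose-response recovery uses
60-patient cohorts; descriptive patterns use 42; the time-of-day mode
check uses 150 (≈3000 sessions) because an argmax over 24 hourly bins
needs a few thousand counts to be stable.

## What passing tests show — and don't

The synthetic generator plants every effect the analysis estimates, so
green tests demonstrate that the estimators are implemented correctly
(planted values are recovered exactly at zero noise and within
Monte-Carlo tolerance at calibrated noise), that the pipeline conserves
minutes and never leaks training information across the temporal split,
and that the classifier solves a clean version of the recognition
problem. They do not demonstrate clinical-grade accuracy: real
recordings carry inter-subject variability, off-protocol activities,
device misuse and dropout that the generator intentionally omits, and a
real deployment would need validation on clinical data. Known
limitations: no repetition counting or technique scoring; no
adversarial activities (swimming, weight training); single local clock
per patient (no timezone arithmetic); NPRS floor clipping mildly
attenuates the planted pain slope; DASH can leave [0, 100] in extreme
synthetic configurations.
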