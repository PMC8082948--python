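# physiotrack

Objective measurement of home physiotherapy participation from
smartwatch inertial sensors, and the downstream clinical analysis that
participation enables.

Patients in shoulder rehabilitation are asked to exercise ~20 minutes a
day at home, but self-reported adherence is unreliable. A wrist-worn
device recording a 9-channel inertial stream (triaxial accelerometer,
gyroscope, magnetometer at 50 Hz) makes participation measurable: a
classifier detects exercise activity window by window, detected windows
become bouts, sessions and daily minutes, and daily minutes become a
**participation ratio**

```
ratio_d = min(detected_minutes_d / 20, 1)
```

whose running mean (×100) is a patient's cumulative participation
percent. The package implements the full chain plus the analyses built
on it, end-to-end testable on synthetic data with known ground truth:

- **`simulate`** — synthetic study conditions: quasi-periodic exercise
  signals vs. daily-living signals, supervised sessions with label
  spans, and whole cohorts (baseline covariates, declining home-session
  schedules with bimodal 10 AM / 9 PM start times, outcome trajectories
  carrying a planted linear dose response).
- **`windowing`** — overlapping 10-s sliding windows, principal-motion
  label simplification, per-patient *temporal* train/test splitting
  (each patient's chronologically last session is held out).
- **`fcn`** — a fully convolutional network for time-series
  classification (temporal conv → batch norm → ReLU, stacked; global
  average pooling; softmax), implemented in NumPy with Adam and
  early stopping; used as a binary exercise detector and a multiclass
  exercise recognizer.
- **`participation`** — bout extraction (median filter + run-length
  encoding + minimum duration), daily roll-ups, adherent-day fraction,
  weekly minutes with an early/late paired-t phase comparison,
  day-of-week and time-of-day patterns.
- **`outcomes`** — DASH (0–100) and 3-item NPRS (0–10) scoring,
  improvement = baseline − follow-up, ordinary least squares
  dose-response `improvement = a + b · participation%`, MCID-based
  participation thresholds `mcid / b`, and univariable adherence
  predictors (Pearson / Spearman / two-sample t by variable type).
- **`pipeline` / CLI** — `physiotrack simulate|prep|train|evaluate|
  track|analyze|report|run`, seeded and configured by YAML, writing
  plain CSV/JSON artifacts per stage.

## Worked example

`examples/04_dose_response.py` simulates a 60-patient cohort with a
planted dose response of 0.37 disability points per participation
percent and residual noise calibrated to a moderate correlation:

```
$ python examples/04_dose_response.py
12-week disability dose response: n=60, slope=0.415 points per participation-%, R=0.43, p=0.001
Participation increase for a clinically important change (10.83 points): 26%
```

The fitted slope recovers the planted 0.37 up to sampling noise, and
dividing the MCID by the slope converts it into a participation
threshold: an increase of roughly a quarter of the daily expectation
(~5–6 minutes per day) is associated with a clinically important
improvement. The other examples cover signal generation, classifier
training, participation tracking, adherence predictors and the full
pipeline (`examples/01…06`).

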