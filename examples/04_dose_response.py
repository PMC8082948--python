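"""Dose-response of outcome improvement on cumulative participation.

Simulates a 60-patient cohort with a planted linear effect (0.37
disability points per participation percent), fits the least-squares
regression at 12 weeks, and converts the slope into the participation
increase associated with a minimal clinically important difference
(MCID, 10.83 disability points).
"""

from physiotrack import CohortSimConfig, gen_cohort
from physiotrack.outcomes import DASH_MCID, dose_response, mcid_threshold

cfg = CohortSimConfig(n_patients=60, seed=42)      # noise tuned to r ~ 0.4
cohort = gen_cohort(cfg)

wide = cohort.outcomes.pivot_table(index="patient_id", columns="week")
improvement = wide[("dash", 0)] - wide[("dash", 12)]
participation = (cohort.true_participation.query("week == 12")
                 .set_index("patient_id").participation_pct
                 .reindex(improvement.index))

fit = dose_response(participation, improvement, timepoint_weeks=12)
print(f"12-week disability dose response: n={fit.n}, "
      f"slope={fit.slope:.3f} points per participation-%, "
      f"R={fit.pearson_r:.2f}, p={fit.p_value:.3f}")

threshold = mcid_threshold(DASH_MCID, fit.slope)
print(f"Participation increase for a clinically important change "
      f"({DASH_MCID} points): {threshold}%")

# With the planted slope 0.37 the fitted slope lands near 0.37 and the
# threshold near 29%: a patient raising participation by ~6 min/day
# is associated with a clinically meaningful disability improvement.
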