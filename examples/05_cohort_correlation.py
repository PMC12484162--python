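"""Cohort analysis: planted HRV-to-time-to-delivery correlations.

A synthetic cohort is generated with monotone relations planted between
HRV and time to delivery (TTD = gestational age at delivery minus at
recording): LF/HF rising toward longer TTD (Spearman +0.55) and RMSSD
falling (-0.50).  Each subject's ECG is processed through the full
pipeline, non-spontaneous deliveries are excluded, and the Spearman table
is computed the way the cohort analysis prescribes.
"""

from laborhrv import CohortSpec, generate_cohort
from laborhrv.cohort import (
    apply_exclusions,
    correlation_table,
    format_correlation_table,
    time_to_delivery,
)
from laborhrv.pipeline import run_pipeline

spec = CohortSpec(
    n_subjects=60,
    effect_map={"lf_hf": 0.55, "rmssd": -0.50},
    seed=5,
)
subjects, truth = generate_cohort(spec)
cohort, corr, report = run_pipeline([s.recording for s in subjects])

print(f"subjects generated   : {spec.n_subjects}")
print(f"analyzed             : {report['n_analyzed']}  (exclusions: {report['exclusions']})")
print()
print(format_correlation_table(corr))
print()
lfhf_r = corr.set_index("metric").loc["lf_hf", "ttd_r"]
rmssd_r = corr.set_index("metric").loc["rmssd", "ttd_r"]
print(f"planted rho(LF/HF, TTD) = +0.55 -> estimated {lfhf_r:+.2f}")
print(f"planted rho(RMSSD, TTD) = -0.50 -> estimated {rmssd_r:+.2f}")
print("At n ~ 50 the sampling error of a Spearman rho is about 0.14, so")
print("estimates this close to the planted values are expected.")
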