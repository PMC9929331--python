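"""From raw conductance traces to the per-participant outcome mSCL.

Each trace is normalized against the mean conductance of the final 5 s of
its pre-script pause (pSCL): nSCL = 100 × (SCL − pSCL) / pSCL, a percent
change.  Per participant, scripts whose imagery-window mean or variance is
outlying under the 1.5·IQR rule are excluded, and mSCL is the mean of the
retained non-test script means.
"""

from sclimagery import (EffectSpec, generate_cohort, normalize_trace,
                        preprocess_cohort, tercile_thresholds)
from dataclasses import replace

# plant one gross outlier script in roughly 1 of 7 scripts per participant
spec = replace(EffectSpec(), outlier_fraction=1 / 7, outlier_magnitude=40.0)
profiles, recordings, truth = generate_cohort(n=30, spec=spec, seed=11)

tr = normalize_trace(recordings[1])
print(f"{tr.participant_id}/{tr.script_id}: pSCL = {tr.pscl:.2f} uS, "
      f"imagery-window mean nSCL = {tr.imagery.mean():+.2f} %")

summaries, outcomes = preprocess_cohort(recordings)
excluded = summaries[~summaries.retained]
flagged = truth.scripts[truth.scripts.is_outlier]
print(f"\nIQR cleaning excluded {len(excluded)} of {len(summaries)} scripts "
      f"({len(flagged)} were planted outliers)")

hits = excluded.merge(flagged, on=["participant_id", "script_id"])
print(f"planted outliers among the exclusions: {len(hits)} / {len(flagged)}")

print(f"\nparticipant outcomes (first 5 of {len(outcomes)}):")
print(outcomes.head().to_string(index=False))

lo, hi = tercile_thresholds(outcomes.mscl)
print(f"\nmSCL tercile thresholds: low < {lo:.2f} <= moderate <= {hi:.2f} < high")
print("(each band covers one third of the cohort)")
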