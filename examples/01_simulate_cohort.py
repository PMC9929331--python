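"""Generate a synthetic imagery cohort and inspect its ground truth.

A cohort is n participants × 7 scripted scenes (one squats test scene plus
six imagery scenes).  Each participant's five trait scores drive a known
percent-SCL-change surface; each scene realizes that value plus scene-level
jitter inside a 40 Hz conductance trace.
"""

import numpy as np

from sclimagery import EffectSpec, generate_cohort, true_surface

spec = EffectSpec()  # default surface: all five traits + one interaction
profiles, recordings, truth = generate_cohort(n=30, spec=spec, seed=11)

print(f"cohort: {len(profiles)} participants, {len(recordings)} recordings")
rec = recordings[0]
print(f"first recording: {rec.participant_id}/{rec.script_id}, "
      f"{rec.samples.size} samples at {rec.fs:g} Hz "
      f"({rec.samples.size / rec.fs:.0f} s), "
      f"imagery window {rec.imagery_start}..{rec.imagery_end}")

p0 = profiles.iloc[0]
print(f"\nparticipant {p0.participant_id}: neuroticism {p0.neuroticism:.2f} "
      f"(normalized {p0.neuroticism_norm:+.2f}), "
      f"general imagery {p0.general_imagery:.2f} "
      f"(normalized {p0.general_imagery_norm:+.2f})")
print(f"true surface value (planted mean %SCL change): "
      f"{true_surface(p0, spec):+.2f}")
print(f"ground-truth mSCL_true: "
      f"{truth.participants.loc[0, 'mscl_true']:+.2f}  "
      "(scene mean incl. jitter)")

print("\nplanted per-script percent changes for this participant:")
first = truth.scripts[truth.scripts.participant_id == p0.participant_id]
for row in first.itertuples():
    tag = " (test scene, excluded from mSCL)" if row.is_test_scene else ""
    print(f"  {row.script_id:<24s} {row.planted_pct:+6.2f}{tag}")

# The spread of true values across the cohort is what the models must learn.
vals = truth.participants.mscl_true
print(f"\ncohort mSCL_true range: {vals.min():+.2f} .. {vals.max():+.2f} "
      f"(SD {np.std(vals):.2f})")
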