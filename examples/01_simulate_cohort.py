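"""Generate a synthetic two-arm VFT cohort and inspect its ground truth.

Builds a small insomnia-trial-like cohort (intervention vs control, pre
and post, 48-channel HbO2 recordings at 5 Hz plus clinical scales) and
prints what was injected: per-subject mean-FC changes and the coupled
PSQI improvements.
"""

import numpy as np

from nirsvft.synth import default_sim_config, simulate_cohort

cfg = default_sim_config(seed=7, n_per_group=4)
cohort = simulate_cohort(cfg)

print(f"recordings: {len(cohort.recordings)} "
      f"({cfg.n_per_group} per group x 2 groups x 2 sessions)")
rec = cohort.recordings[0]
print(f"one recording: {rec.subject_id} {rec.timepoint}, "
      f"{rec.n_channels} channels x {rec.n_samples} samples @ {rec.fs} Hz")

print("\nclinical scales (first rows):")
print(cohort.scales.head(4).to_string(index=False))

print("\nground truth per subject (mean-FC change, r units):")
for sid, t in sorted(cohort.truth.subjects.items()):
    print(f"  {sid} ({t.group:12s}): model-implied {t.delta_mean_fc:+.3f}, "
          f"pipeline-observable {t.delta_measured:+.3f}")

ints = [t.delta_measured for t in cohort.truth.subjects.values()
        if t.group == "intervention"]
ctls = [t.delta_measured for t in cohort.truth.subjects.values()
        if t.group == "control"]
print(f"\nmean observable dFC: intervention {np.mean(ints):+.3f}, "
      f"control {np.mean(ctls):+.3f}")
print("(the intervention group carries the larger injected connectivity gain;")
print(" PSQI improvements are coupled to the observable dFC at r = "
      f"{cfg.coupling_r})")
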