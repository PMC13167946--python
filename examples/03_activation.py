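"""Channel and ROI task-activation statistics on a simulated cohort.

Runs the block-contrast -> paired-t -> BH-FDR chain and the ROI table
(within-group change, between-group comparison with Cohen's d).
"""

from nirsvft.activation import channel_activation_tests, cohort_contrasts, roi_tests
from nirsvft.preprocess import preprocess_recording
from nirsvft.synth import default_sim_config, simulate_cohort

cfg = default_sim_config(seed=12, n_per_group=16)
cohort = simulate_cohort(cfg)

processed, quality = [], {}
for rec in cohort.recordings:
    prec, rep = preprocess_recording(rec, cfg.paradigm)
    processed.append(prec)
    quality[(rec.subject_id, rec.timepoint)] = rep

contrasts = cohort_contrasts(processed, cfg.paradigm, quality=quality)

tmap = channel_activation_tests(contrasts, "intervention", mode="pre_vs_post")
sig = tmap[tmap["significant"]]
print(f"intervention pre->post: {len(sig)}/48 channels significant after "
      f"BH-FDR (q < 0.05)")
print(sig[["channel_id", "t", "p", "q", "mean_change"]].head(8).to_string(index=False))

roi = roi_tests(contrasts, cfg.montage)
print("\nROI table (change = post - pre task contrast, mmol/L*mm):")
cols = ["roi", "g1_change", "g1_p", "g2_change", "g2_p", "between_p", "effect_size"]
print(roi[cols].round(4).to_string(index=False))
print("(g1 = intervention, g2 = control; the generator injects the larger")
print(" amplitude increments in frontal ROIs of the intervention group)")
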