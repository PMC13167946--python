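"""Preprocess one noisy recording: motion repair, 0.1 Hz low-pass, panning.

Shows the pipeline cleaning a simulated recording that carries spikes,
baseline shifts, cardiac/respiratory/Mayer oscillations and drift, and
compares the task-minus-baseline contrast before and after.
"""

from nirsvft.preprocess import PreprocConfig, detect_motion, preprocess_recording
from nirsvft.synth import default_sim_config, simulate_recording

cfg = default_sim_config(seed=3, n_per_group=2)
paradigm = cfg.paradigm
rec = simulate_recording(cfg, 0, "intervention", "post")

mask = detect_motion(rec, PreprocConfig())
print(f"raw recording: {rec.n_channels} channels, {rec.duration_s:.0f} s")
print(f"motion artifacts flagged on {int((mask.any(axis=1)).sum())} channels "
      f"({100 * mask.mean():.1f}% of samples)")

clean, report = preprocess_recording(rec, paradigm)
print(f"quality: {report.n_good}/48 good channels "
      f"(session gate >= {report.min_good_channels}: "
      f"{'pass' if report.subject_valid else 'fail'})")


def contrast(r):
    return (r.data[:, paradigm.task_slice].mean(axis=1)
            - r.data[:, paradigm.baseline_slice].mean(axis=1))


raw_c, clean_c = contrast(rec), contrast(clean)
print(f"task-minus-baseline contrast, channel-mean: "
      f"raw {raw_c.mean():+.4f} -> preprocessed {clean_c.mean():+.4f} mmol/L*mm")
print(f"channel-sd of contrast: raw {raw_c.std():.4f} -> {clean_c.std():.4f}")
print("(filtering and artifact repair shrink nuisance spread while the")
print(" block-design activation survives; panning re-zeroes each channel")
print(" on the minimum of the last 10 s of pre-task rest)")
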