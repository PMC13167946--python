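import numpy as np
import pytest
from dataclasses import replace

from nirsvft.preprocess import (
    MBLLParams,
    PreprocConfig,
    assess_quality,
    baseline_pan,
    correct_motion,
    detect_motion,
    emit_intensity,
    lowpass,
    mbll_convert,
    preprocess_recording,
    subject_valid,
)
from nirsvft.recording import Recording
from nirsvft.synth import ArtifactSpec, NoiseSpec, default_sim_config, simulate_recording, task_regressor


def make_rec(data, fs=5.0, **kw):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    defaults = dict(subject_id="s", group="control", timepoint="pre",
                    fs=fs, channel_ids=tuple(range(1, data.shape[0] + 1)))
    defaults.update(kw)
    return Recording(data=data, **defaults)


CFG = PreprocConfig()


# ---------------------------------------------------------------------------
# MBLL
# ---------------------------------------------------------------------------

def test_constant_intensity_converts_to_zero_concentration():
    inten = np.full((2, 3, 700), 0.8)
    rec = make_rec(np.zeros((3, 700)))
    rec.intensity = inten
    out = mbll_convert(rec, CFG)
    assert np.allclose(out.data, 0.0)


def test_mbll_round_trips_the_emission_model():
    rng = np.random.default_rng(0)
    hbo = rng.normal(0.0, 0.05, (48, 700))
    inten, hbr = emit_intensity(hbo, CFG.mbll, i0=1.0)
    rec = make_rec(np.zeros((48, 700)))
    rec.intensity = inten
    rec.i0 = np.ones((2, 48))
    out = mbll_convert(rec, CFG)
    assert np.abs(out.data - hbo).max() < 1e-9
    assert np.abs(out.hbr - hbr).max() < 1e-9


def test_singular_extinction_system_is_rejected():
    bad = MBLLParams(extinction=((0.1, 0.2), (0.2, 0.4)))
    with pytest.raises(ValueError, match="singular"):
        bad.matrix()


def test_nonpositive_intensity_is_rejected():
    rec = make_rec(np.zeros((2, 700)))
    rec.intensity = np.zeros((2, 2, 700))
    with pytest.raises(ValueError, match="positive"):
        mbll_convert(rec, CFG)


# ---------------------------------------------------------------------------
# Motion
# ---------------------------------------------------------------------------

def test_constant_signal_has_empty_mask():
    rec = make_rec(np.full((4, 700), 2.5))
    assert not detect_motion(rec, CFG).any()


def test_large_spike_is_masked():
    rng = np.random.default_rng(1)
    x = rng.normal(0.0, 0.05, (2, 700))
    x[1, 300] += 20 * 0.05
    rec = make_rec(x)
    mask = detect_motion(rec, CFG)
    assert mask[1, 300]
    assert not mask[0].any()


def test_infinite_threshold_disables_detection():
    rng = np.random.default_rng(2)
    rec = make_rec(rng.normal(0, 1, (2, 700)))
    cfg = replace(CFG, motion_z_threshold=np.inf)
    assert not detect_motion(rec, cfg).any()


def test_empty_mask_is_identity():
    rng = np.random.default_rng(3)
    rec = make_rec(rng.normal(0, 1, (3, 700)))
    out = correct_motion(rec, np.zeros((3, 700), dtype=bool))
    assert np.array_equal(out.data, rec.data)


def test_cubic_repair_is_exact_on_a_linear_ramp():
    ramp = np.tile(np.linspace(0.0, 1.0, 700), (2, 1))
    spiked = ramp.copy()
    spiked[0, 350] += 5.0
    rec = make_rec(spiked)
    mask = detect_motion(rec, CFG)
    assert mask[0, 350]
    out = correct_motion(rec, mask)
    assert np.abs(out.data - ramp).max() < 1e-6


def test_fully_masked_channel_is_an_error():
    rec = make_rec(np.random.default_rng(4).normal(0, 1, (2, 700)))
    mask = np.zeros((2, 700), dtype=bool)
    mask[0] = True
    with pytest.raises(ValueError, match="fully masked"):
        correct_motion(rec, mask)


# ---------------------------------------------------------------------------
# Low-pass filter
# ---------------------------------------------------------------------------

def test_dc_gain_is_unity():
    rec = make_rec(np.full((2, 700), 3.7))
    out = lowpass(rec, CFG)
    assert np.abs(out.data - 3.7).max() < 1e-8


def _sine_response(freq, duration_s=600.0, fs=5.0):
    t = np.arange(int(duration_s * fs)) / fs
    rec = make_rec(np.sin(2 * np.pi * freq * t))
    out = lowpass(rec, CFG)
    core = out.data[0][len(t) // 4: 3 * len(t) // 4]
    return np.abs(core).max()


def test_cardiac_band_is_suppressed():
    assert _sine_response(1.1) < 0.01


def test_infraslow_band_passes():
    assert _sine_response(0.01) > 0.99


def test_filter_is_linear():
    rng = np.random.default_rng(5)
    x, y = rng.normal(0, 1, (2, 700))
    a, b = 1.7, -0.4
    fx = lowpass(make_rec(x), CFG).data[0]
    fy = lowpass(make_rec(y), CFG).data[0]
    fxy = lowpass(make_rec(a * x + b * y), CFG).data[0]
    assert np.abs(fxy - (a * fx + b * fy)).max() < 1e-8


def test_unstable_design_is_rejected():
    rec = make_rec(np.zeros(700))
    with pytest.raises(ValueError, match="Nyquist|cutoff"):
        lowpass(rec, replace(CFG, lowpass_cutoff_hz=2.5))


# ---------------------------------------------------------------------------
# Panning
# ---------------------------------------------------------------------------

def test_pan_zeroes_a_constant_signal(paradigm):
    rec = make_rec(np.full((2, 700), 0.9))
    out = baseline_pan(rec, paradigm, CFG)
    assert np.all(out.data == 0.0)


def test_pan_window_minimum_becomes_exactly_zero(paradigm):
    rng = np.random.default_rng(6)
    rec = make_rec(rng.normal(0, 1, (4, 700)))
    out = baseline_pan(rec, paradigm, CFG)
    win = out.data[:, paradigm.pan_slice(CFG.baseline_tail_s)]
    assert np.all(win.min(axis=1) == 0.0)


def test_pan_shifts_by_the_window_minimum(paradigm):
    x = np.zeros((1, 700))
    x[0, paradigm.pan_slice(10.0)] = np.linspace(-0.3, 0.5, 50)
    rec = make_rec(x)
    out = baseline_pan(rec, paradigm, CFG)
    assert np.allclose(out.data, x + 0.3)


def test_pan_is_idempotent(paradigm):
    rng = np.random.default_rng(7)
    rec = make_rec(rng.normal(0, 1, (3, 700)))
    once = baseline_pan(rec, paradigm, CFG)
    twice = baseline_pan(once, paradigm, CFG)
    assert np.array_equal(once.data, twice.data)


# ---------------------------------------------------------------------------
# Quality
# ---------------------------------------------------------------------------

def test_clean_simulated_recording_has_48_good_channels(paradigm):
    rec = simulate_recording(default_sim_config(seed=2, n_per_group=2), 0,
                             "intervention", "pre")
    rep = assess_quality(rec, CFG)
    assert rep.n_good == 48
    assert rep.subject_valid


@pytest.mark.parametrize("n_flat,valid", [(13, False), (12, True)])
def test_good_channel_gate_boundary(paradigm, n_flat, valid):
    """>= 36 good channels is inclusive: 36 passes, 35 fails."""
    rec = simulate_recording(default_sim_config(seed=2, n_per_group=2), 0,
                             "intervention", "pre")
    data = rec.data.copy()
    data[:n_flat] = 0.0
    flat = rec.copy_with(data)
    rep = assess_quality(flat, CFG)
    assert rep.n_good == 48 - n_flat
    assert rep.subject_valid is valid
    good_rep = assess_quality(rec, CFG)
    assert subject_valid(good_rep, rep) is valid


# ---------------------------------------------------------------------------
# Pipeline-level properties
# ---------------------------------------------------------------------------

def test_spike_artifacts_barely_move_the_task_contrast(paradigm):
    """With default spike rates, preprocessing keeps the task-minus-
    baseline contrast within 10% of the injected amplitude."""
    a = 0.05
    amps = tuple((("intervention", tp, roi), a) for tp in ("pre", "post")
                 for roi in ("rSFC", "lSFC", "rDLPFC", "lDLPFC", "rSTC",
                             "lSTC", "rVLPFC", "lVLPFC", "mPFC"))
    cfg = default_sim_config(
        seed=13, n_per_group=2,
        activation_amplitude=amps,
        amplitude_between_sd=0.0, amplitude_session_sd=0.0,
        slow_scale=0.0,
        noise=NoiseSpec(white_sd=0.0, ar1_coef=0.0, oscillations=(),
                        drift_slope_sd=0.0),
        artifact=ArtifactSpec(spike_rate_per_min=1.0, spike_amplitude_sd=0.5,
                              shift_rate_per_min=0.0, shift_amplitude_sd=0.0),
    )
    rec = simulate_recording(cfg, 0, "intervention", "pre")
    prec, _ = preprocess_recording(rec, paradigm, CFG)
    x_f = lowpass(make_rec(task_regressor(paradigm)), CFG).data[0]
    expected = a * (x_f[paradigm.task_slice].mean() - x_f[paradigm.baseline_slice].mean())
    contrast = (prec.data[:, paradigm.task_slice].mean(axis=1)
                - prec.data[:, paradigm.baseline_slice].mean(axis=1))
    assert np.abs(contrast - expected).max() < 0.1 * a


def test_pipeline_order_is_logged(paradigm):
    rec = simulate_recording(default_sim_config(seed=2, n_per_group=2), 0,
                             "control", "pre")
    prec, rep = preprocess_recording(rec, paradigm)
    assert prec.meta["pipeline"] == "mbll?>motion>lowpass>pan"
    assert rep.n_good <= 48


def test_quality_assessment_is_deterministic(paradigm):
    rec = simulate_recording(default_sim_config(seed=4, n_per_group=2), 1,
                             "control", "post")
    r1 = assess_quality(rec, CFG)
    r2 = assess_quality(rec, CFG)
    assert np.array_equal(r1.good, r2.good)
    assert np.array_equal(r1.scores, r2.scores)
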