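"""Synthetic two-group, two-timepoint VFT cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* block-design HbO2 responses — a canonical double-gamma HRF convolved
  with the three-block boxcar, scaled by region-specific amplitudes
  (defaults calibrated to the trial's printed per-ROI task contrasts);
* community-structured inter-channel correlation — a latent-factor model
  with one global factor, one per-ROI factor, and one "executive"
  factor spanning lSFC+lDLPFC+mPFC+rDLPFC whose loading increases after
  the intervention (this is what creates group x time FC increments);
* physiological noise (Mayer, respiratory and cardiac oscillations,
  AR(1) broadband noise, slow drift) and motion artifacts (spikes and
  baseline shifts), injected after signal composition so preprocessing
  has real work to do;
* clinical scales whose PSQI improvement is linearly coupled to each
  subject's mean-FC change (the pipeline-observable change when
  recordings are rendered) at a configurable population correlation.

Every subject's model-implied ("ground-truth") task contrast and
functional-connectivity matrix under the default preprocessing is
returned alongside the data, so parameter-recovery tests can compare
estimates against what was actually injected.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .montage import ROI_NAMES, Montage, default_montage
from .paradigm import Paradigm
from .preprocess import PreprocConfig, emit_intensity, lowpass_sos
from .recording import GROUPS, TIMEPOINTS, Recording

__all__ = [
    "HRFParams",
    "Oscillation",
    "NoiseSpec",
    "ArtifactSpec",
    "Community",
    "ScaleSpec",
    "SimConfig",
    "Cohort",
    "CohortTruth",
    "SubjectTruth",
    "hrf",
    "task_regressor",
    "simulate_recording",
    "simulate_cohort",
    "default_sim_config",
    "ModelExpectations",
    "SCALE_COLUMNS",
]


# ---------------------------------------------------------------------------
# Hemodynamic response
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma HRF: peak 6 s, undershoot 16 s, ratio 1:6."""

    peak_s: float = 6.0
    undershoot_s: float = 16.0
    undershoot_ratio: float = 1.0 / 6.0
    dispersion: float = 1.0

    def __post_init__(self) -> None:
        if self.peak_s <= 0 or self.undershoot_s <= 0 or self.dispersion <= 0:
            raise ValueError("invalid HRF shape parameters")
        if self.undershoot_ratio < 0:
            raise ValueError("undershoot ratio must be >= 0")


def hrf(t, params: HRFParams = HRFParams()) -> np.ndarray:
    """Double-gamma response, unit positive peak, h(0) = 0."""
    t = np.asarray(t, dtype=float)
    a1 = params.peak_s / params.dispersion + 1.0
    a2 = params.undershoot_s / params.dispersion + 1.0
    g1 = stats.gamma.pdf(t, a=a1, scale=params.dispersion)
    g1 /= stats.gamma.pdf(params.peak_s, a=a1, scale=params.dispersion)
    g2 = stats.gamma.pdf(t, a=a2, scale=params.dispersion)
    g2 /= stats.gamma.pdf(params.undershoot_s, a=a2, scale=params.dispersion)
    return g1 - params.undershoot_ratio * g2


def task_regressor(paradigm: Paradigm, params: HRFParams = HRFParams()) -> np.ndarray:
    """Boxcar of the task blocks convolved with the HRF, rescaled to peak 1.

    Zero before task onset (causality); identically zero when the
    paradigm has no task blocks.
    """
    n = paradigm.n_samples
    box = np.zeros(n)
    box[paradigm.task_slice] = 1.0
    if not box.any():
        return box
    kern_t = np.arange(0, 32.0 + params.undershoot_s, 1.0 / paradigm.fs)
    kern = hrf(kern_t, params)
    reg = np.convolve(box, kern)[:n] / paradigm.fs
    peak = reg.max()
    return reg / peak if peak > 0 else reg


# ---------------------------------------------------------------------------
# Config dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Oscillation:
    freq_hz: float
    amplitude: float
    random_phase: bool = True


@dataclass(frozen=True)
class NoiseSpec:
    """Structured noise. Slow structured components (latents and the
    idiosyncratic factor residual) share one spectrum — white noise
    shaped by a low-pass at ``slow_cutoff_hz`` — so that linear
    filtering in preprocessing leaves their correlations untouched.
    ``slow_cutoff_hz=None`` leaves them white (used by model-law tests).
    """

    white_sd: float = 0.05
    ar1_coef: float = 0.3
    oscillations: tuple[Oscillation, ...] = (
        Oscillation(0.10, 0.02),   # Mayer waves
        Oscillation(0.25, 0.02),   # respiration
        Oscillation(1.10, 0.04),   # cardiac
    )
    drift_slope_sd: float = 2e-4   # mmol/L.mm per second
    slow_cutoff_hz: float | None = 0.08

    def validate(self, fs: float) -> None:
        if self.white_sd < 0 or self.drift_slope_sd < 0:
            raise ValueError("noise sds must be >= 0")
        if not 0 <= self.ar1_coef < 1:
            raise ValueError("ar1_coef must be in [0, 1)")
        for o in self.oscillations:
            if not 0 < o.freq_hz < fs / 2:
                raise ValueError("oscillation frequencies must be below Nyquist")


@dataclass(frozen=True)
class ArtifactSpec:
    spike_rate_per_min: float = 1.0
    spike_amplitude_sd: float = 0.5
    shift_rate_per_min: float = 0.05
    shift_amplitude_sd: float = 0.03

    def __post_init__(self) -> None:
        if self.spike_rate_per_min < 0 or self.shift_rate_per_min < 0:
            raise ValueError("artifact rates must be >= 0")


@dataclass(frozen=True)
class Community:
    """A set of channels sharing one latent factor.

    ``baseline_loading`` applies at the pre timepoint in both groups;
    at post, each subject receives a loading increment drawn from the
    group's normal distribution (clipped so loadings stay in [0, 1)).
    """

    name: str
    channels: frozenset[int]
    baseline_loading: float
    increment_mean: tuple[tuple[str, float], ...] = ()
    increment_sd: tuple[tuple[str, float], ...] = ()
    #: number of independent latents carrying this community's shared
    #: variance (loading w is split as w/sqrt(n) per latent, leaving all
    #: correlations unchanged while averaging down estimation error —
    #: "global physiology" is many processes, not one)
    n_factors: int = 1

    def inc_mean(self, group: str) -> float:
        return dict(self.increment_mean).get(group, 0.0)

    def inc_sd(self, group: str) -> float:
        return dict(self.increment_sd).get(group, 0.0)


@dataclass(frozen=True)
class ScaleSpec:
    """Per-group baseline and pre->post improvement distribution of a scale."""

    baseline_mean: tuple[tuple[str, float], ...]
    baseline_sd: tuple[tuple[str, float], ...]
    improvement_mean: tuple[tuple[str, float], ...]
    improvement_sd: tuple[tuple[str, float], ...]
    lo: float
    hi: float
    integer: bool = True


SCALE_COLUMNS = (
    "psqi_total",
    "psqi_sleep_quality",
    "psqi_latency",
    "psqi_duration",
    "psqi_efficiency",
    "psqi_disturbance",
    "psqi_daytime",
    "sds",
    "sas",
    "pss14",
)


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_per_group: int = 32
    montage: Montage = field(default_factory=default_montage)
    paradigm: Paradigm = field(default_factory=Paradigm)
    hrf: HRFParams = field(default_factory=HRFParams)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    # task activation: mean amplitude per (group, timepoint, roi), in
    # mmol/L.mm at the HRF peak, plus subject/session jitter (per ROI)
    activation_amplitude: tuple[tuple[tuple[str, str, str], float], ...] = ()
    amplitude_between_sd: float = 0.06
    amplitude_session_sd: float = 0.04
    slow_scale: float = 0.03  # mmol/L.mm per unit latent
    fc_communities: tuple[Community, ...] = ()
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    artifact: ArtifactSpec = field(default_factory=ArtifactSpec)
    coupling_r: float = 0.5  # population corr(PSQI improvement, ground-truth dFC)
    scales: tuple[tuple[str, ScaleSpec], ...] = ()
    groups: tuple[str, ...] = GROUPS
    emit_intensity: bool = False
    n_truth_mc: int = 2048

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        self.noise.validate(self.paradigm.fs)
        for (_, _, _), a in self.activation_amplitude:
            if not np.isfinite(a):
                raise ValueError("amplitudes must be finite")
        for c in self.fc_communities:
            if not 0 <= c.baseline_loading < 1:
                raise ValueError("baseline loadings must be in [0, 1)")
        if not -1 < self.coupling_r < 1:
            raise ValueError("coupling_r must be in (-1, 1)")

    def amplitude(self, group: str, timepoint: str, roi: str) -> float:
        return dict(self.activation_amplitude).get((group, timepoint, roi), 0.0)


def _per_group(int_val: float, ctl_val: float) -> tuple[tuple[str, float], ...]:
    return (("intervention", int_val), ("control", ctl_val))


def _default_scales() -> tuple[tuple[str, ScaleSpec], ...]:
    # Baselines and improvements follow the trial's printed group means;
    # improvement sds are recovered from the printed 95% CIs (n=32).
    def spec(bm, bs, im, isd, lo, hi):
        return ScaleSpec(
            baseline_mean=_per_group(*bm), baseline_sd=_per_group(*bs),
            improvement_mean=_per_group(*im), improvement_sd=_per_group(*isd),
            lo=lo, hi=hi,
        )

    return (
        ("psqi_total", spec((13.25, 12.88), (2.91, 2.81), (4.69, 2.13), (3.76, 1.96), 0, 21)),
        ("psqi_sleep_quality", spec((2.41, 2.47), (0.56, 0.67), (1.38, 0.81), (0.79, 0.60), 0, 3)),
        ("psqi_latency", spec((2.28, 2.13), (0.52, 0.61), (0.50, 0.03), (0.72, 0.40), 0, 3)),
        ("psqi_duration", spec((2.47, 2.25), (0.57, 0.57), (0.88, 0.50), (0.83, 0.50), 0, 3)),
        ("psqi_efficiency", spec((2.41, 2.25), (0.62, 0.57), (0.94, 0.47), (0.87, 0.50), 0, 3)),
        ("psqi_disturbance", spec((1.72, 1.72), (0.96, 1.09), (0.38, 0.03), (0.76, 0.54), 0, 3)),
        ("psqi_daytime", spec((1.97, 2.06), (0.82, 0.67), (0.63, 0.28), (0.87, 0.58), 0, 3)),
        ("sds", spec((52.16, 54.81), (12.73, 14.10), (7.78, 3.31), (7.66, 8.06), 25, 100)),
        ("sas", spec((47.88, 50.31), (11.32, 16.50), (8.63, 4.38), (7.37, 7.17), 25, 100)),
        ("pss14", spec((42.56, 41.38), (7.12, 7.53), (4.38, 1.94), (7.59, 5.27), 14, 70)),
    )


# Per-ROI task-contrast means (baseline, change) taken from the trial's
# ROI activation table, per group. Amplitudes are specified at HRF peak;
# the realized task-window contrast is amplitude x contrast factor.
_ROI_BASE_INT = {
    "rSFC": 0.033, "lSFC": -0.018, "rDLPFC": 0.001, "lDLPFC": -0.024, "rSTC": 0.040,
    "lSTC": -0.018, "rVLPFC": -0.006, "lVLPFC": -0.011, "mPFC": -0.018,
}
_ROI_CHG_INT = {
    "rSFC": 0.026, "lSFC": 0.059, "rDLPFC": 0.048, "lDLPFC": 0.066, "rSTC": 0.000,
    "lSTC": 0.032, "rVLPFC": 0.063, "lVLPFC": 0.047, "mPFC": 0.075,
}
_ROI_BASE_CTL = {
    "rSFC": 0.003, "lSFC": -0.014, "rDLPFC": -0.017, "lDLPFC": -0.026, "rSTC": 0.037,
    "lSTC": -0.004, "rVLPFC": -0.015, "lVLPFC": 0.009, "mPFC": -0.014,
}
_ROI_CHG_CTL = {
    "rSFC": 0.034, "lSFC": 0.028, "rDLPFC": 0.048, "lDLPFC": 0.047, "rSTC": 0.012,
    "lSTC": 0.023, "rVLPFC": 0.065, "lVLPFC": 0.035, "mPFC": 0.047,
}

#: ROIs whose shared "executive" latent gains loading post-intervention.
EXEC_ROIS = ("lSFC", "lDLPFC", "mPFC", "rDLPFC")


def _default_amplitudes() -> tuple[tuple[tuple[str, str, str], float], ...]:
    out = []
    for roi in ROI_NAMES:
        out.append((("intervention", "pre", roi), _ROI_BASE_INT[roi]))
        out.append((("intervention", "post", roi), _ROI_BASE_INT[roi] + _ROI_CHG_INT[roi]))
        out.append((("control", "pre", roi), _ROI_BASE_CTL[roi]))
        out.append((("control", "post", roi), _ROI_BASE_CTL[roi] + _ROI_CHG_CTL[roi]))
    return tuple(out)


def default_communities(montage: Montage) -> tuple[Community, ...]:
    """Global + per-ROI + executive-network latent communities.

    The global loading increment dominates the cohort-wide mean-FC rise
    (larger in the intervention group); the executive community adds the
    extra frontal ROI-pair enhancement. Increment spreads are calibrated
    so the between-subject sd of the measured mean-FC change matches the
    trial's printed 0.120 +/- 0.046.
    """
    rois = montage.rois
    all_ch = frozenset(range(1, 49))
    exec_ch = frozenset(itertools.chain.from_iterable(rois[r] for r in EXEC_ROIS))
    comms = [
        Community("global", all_ch, 0.75,
                  increment_mean=_per_group(0.20, 0.06),
                  increment_sd=_per_group(0.09, 0.09), n_factors=8),
        Community("executive", exec_ch, 0.35,
                  increment_mean=_per_group(0.10, 0.02),
                  increment_sd=_per_group(0.05, 0.05), n_factors=4),
    ]
    for roi in ROI_NAMES:
        comms.append(Community(f"roi:{roi}", frozenset(rois[roi]), 0.65, n_factors=2))
    return tuple(comms)


def default_sim_config(seed: int = 0, n_per_group: int = 32, **overrides) -> SimConfig:
    """The study-conditions configuration (trial-calibrated defaults)."""
    montage = overrides.pop("montage", default_montage())
    kw = dict(
        activation_amplitude=_default_amplitudes(),
        fc_communities=default_communities(montage),
        scales=_default_scales(),
    )
    kw.update(overrides)
    return SimConfig(seed=seed, n_per_group=n_per_group, montage=montage, **kw)


# ---------------------------------------------------------------------------
# Model-implied expectations
# ---------------------------------------------------------------------------

class ModelExpectations:
    """Population moments of the preprocessed signal under a SimConfig.

    All slow structured components share one spectrum, so their mutual
    correlations survive linear filtering; broadband noise, oscillations
    and drift only add (filter-attenuated) variance to the denominators.
    Gains are computed by numerical integration of |H|^4 (zero-phase
    filtering applies the Butterworth magnitude twice).
    """

    _N_FREQ = 4096

    def __init__(self, cfg: SimConfig):
        self.cfg = cfg
        p = cfg.paradigm
        freqs = np.linspace(0.0, p.fs / 2, self._N_FREQ + 1)[1:]
        pp_sos = lowpass_sos(cfg.preproc, p.fs)
        g2_pp = self._gain2(pp_sos, freqs, p.fs)
        # expected *windowed* sample variance: subtracting the task-window
        # mean suppresses power below ~1/T (Dirichlet kernel of the mean)
        n_win = p.task_offset - p.task_onset
        dt = 1.0 / p.fs
        w2 = (np.sin(np.pi * freqs * n_win * dt) / (n_win * np.sin(np.pi * freqs * dt))) ** 2
        win = (n_win / (n_win - 1)) * (1.0 - w2)
        noise = cfg.noise
        if noise.slow_cutoff_hz is not None:
            slow_sos = sps.butter(2, noise.slow_cutoff_hz, btype="low", fs=p.fs, output="sos")
            g2_slow = self._gain2(slow_sos, freqs, p.fs)
            self.slow_norm_sd = float(np.sqrt(np.mean(g2_slow**2)))
            slow_rel = g2_slow**2 / np.mean(g2_slow**2)
        else:
            self.slow_norm_sd = 1.0
            slow_rel = np.ones_like(freqs)
        #: task-window variance of a unit-variance slow latent after preprocessing
        self.v_latent = float(np.mean(slow_rel * g2_pp**2 * win))
        # AR(1) broadband
        a = noise.ar1_coef
        theta = 2 * np.pi * freqs / p.fs
        ar_psd = 1.0 / (1.0 - 2 * a * np.cos(theta) + a**2)
        self.v_broadband = float(noise.white_sd**2 * np.mean(ar_psd * g2_pp**2 * win))
        # oscillations (independent random phases per channel)
        v_osc = 0.0
        for o in noise.oscillations:
            g = np.interp(o.freq_hz, freqs, g2_pp)
            wf = np.interp(o.freq_hz, freqs, win)
            v_osc += 0.5 * o.amplitude**2 * g**2 * wf
        self.v_osc = float(v_osc)
        # drift: filter the actual ramp, variance over the task window
        t = p.times()
        ramp = sps.sosfiltfilt(pp_sos, t)
        self.s_drift = float(ramp[p.task_slice].var())
        self.v_drift = noise.drift_slope_sd**2 * self.s_drift
        # task regressor through the same filter
        x = task_regressor(p, cfg.hrf)
        xf = sps.sosfiltfilt(pp_sos, x)
        self.s_task = float(xf[p.task_slice].var())
        self.contrast_factor = float(xf[p.task_slice].mean() - xf[p.baseline_slice].mean())
        self.contrast_factor_raw = float(x[p.task_slice].mean() - x[p.baseline_slice].mean())
        self._x_filtered = xf

    @staticmethod
    def _gain2(sos: np.ndarray, freqs: np.ndarray, fs: float) -> np.ndarray:
        _, h = sps.sosfreqz(sos, worN=freqs, fs=fs)
        return np.abs(h) ** 2

    # -- per-subject expectations ---------------------------------------
    def pair_rho(self, amp: np.ndarray, loadings: np.ndarray) -> np.ndarray:
        """Expected 48x48 Pearson matrix over the task window.

        ``amp``: per-channel HRF-peak amplitude; ``loadings``: (48, K)
        latent loading matrix.
        """
        s2v = self.cfg.slow_scale**2 * self.v_latent
        num = np.outer(amp, amp) * self.s_task + s2v * (loadings @ loadings.T)
        v = (
            amp**2 * self.s_task
            + s2v * ((loadings**2).sum(axis=1) + 1.0)
            + self.v_broadband
            + self.v_osc
            + self.v_drift
        )
        rho = num / np.sqrt(np.outer(v, v))
        np.fill_diagonal(rho, 1.0)
        return rho

    def mean_fc(self, amp: np.ndarray, loadings: np.ndarray) -> tuple[float, float]:
        """(mean Fisher-z, back-transformed mean r) over the 1128 pairs."""
        rho = self.pair_rho(amp, loadings)
        iu = np.triu_indices(rho.shape[0], k=1)
        z = np.arctanh(np.clip(rho[iu], -0.999999, 0.999999))
        mz = float(z.mean())
        return mz, float(np.tanh(mz))

    def expected_contrast(self, amp: np.ndarray, filtered: bool = True) -> np.ndarray:
        f = self.contrast_factor if filtered else self.contrast_factor_raw
        return amp * f


_EXPECT_CACHE: dict[str, ModelExpectations] = {}


def _expectations(cfg: SimConfig) -> ModelExpectations:
    key = repr((
        cfg.paradigm, cfg.hrf, cfg.noise, cfg.slow_scale,
        cfg.preproc.lowpass_cutoff_hz, cfg.preproc.filter_order, cfg.preproc.zero_phase,
    ))
    if key not in _EXPECT_CACHE:
        _EXPECT_CACHE[key] = ModelExpectations(cfg)
    return _EXPECT_CACHE[key]


# ---------------------------------------------------------------------------
# Subject-level parameter draws
# ---------------------------------------------------------------------------

@dataclass
class SubjectParams:
    subject_id: str
    group: str
    amp: dict  # timepoint -> (48,) amplitudes
    loadings: dict  # timepoint -> (48, K) loading matrix
    increments: dict  # community name -> post loading increment


def _loading_matrix(cfg: SimConfig, increments: dict[str, float] | None) -> np.ndarray:
    k = sum(c.n_factors for c in cfg.fc_communities)
    w = np.zeros((48, k))
    col = 0
    for comm in cfg.fc_communities:
        val = comm.baseline_loading + (increments or {}).get(comm.name, 0.0)
        val = float(np.clip(val, 0.0, 0.999)) / np.sqrt(comm.n_factors)
        idx = np.fromiter((c - 1 for c in comm.channels), dtype=int)
        for _ in range(comm.n_factors):
            w[idx, col] = val
            col += 1
    return w


def _draw_subject(cfg: SimConfig, subject_id: str, group: str, rng: np.random.Generator) -> SubjectParams:
    roi_of = np.array([cfg.montage.roi_of(c) for c in range(1, 49)])
    between = {roi: rng.normal(0.0, cfg.amplitude_between_sd) for roi in ROI_NAMES}
    amp = {}
    for tp in TIMEPOINTS:
        session = {roi: rng.normal(0.0, cfg.amplitude_session_sd) for roi in ROI_NAMES}
        amp[tp] = np.array([
            cfg.amplitude(group, tp, roi) + between[roi] + session[roi] for roi in roi_of
        ])
    increments = {
        comm.name: rng.normal(comm.inc_mean(group), comm.inc_sd(group))
        for comm in cfg.fc_communities
        if comm.inc_mean(group) != 0.0 or comm.inc_sd(group) != 0.0
    }
    loadings = {
        "pre": _loading_matrix(cfg, None),
        "post": _loading_matrix(cfg, increments),
    }
    return SubjectParams(subject_id, group, amp, loadings, increments)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _slow_shaped(rng: np.random.Generator, shape: tuple, cfg: SimConfig,
                 exp: ModelExpectations) -> np.ndarray:
    """Unit-variance latent/idiosyncratic noise with the shared slow spectrum."""
    w = rng.standard_normal(shape)
    if cfg.noise.slow_cutoff_hz is None:
        return w
    sos = sps.butter(2, cfg.noise.slow_cutoff_hz, btype="low", fs=cfg.paradigm.fs, output="sos")
    return sps.sosfiltfilt(sos, w, axis=-1) / exp.slow_norm_sd


def _render(cfg: SimConfig, sp: SubjectParams, timepoint: str,
            rng: np.random.Generator) -> Recording:
    p = cfg.paradigm
    n = p.n_samples
    exp = _expectations(cfg)
    t = p.times()
    x = task_regressor(p, cfg.hrf)
    w = sp.loadings[timepoint]
    k = w.shape[1]
    data = sp.amp[timepoint][:, None] * x[None, :]
    if k:
        latents = _slow_shaped(rng, (k, n), cfg, exp)
        data = data + cfg.slow_scale * (w @ latents)
    idio = _slow_shaped(rng, (48, n), cfg, exp)
    data = data + cfg.slow_scale * idio
    noise = cfg.noise
    if noise.white_sd > 0:
        e = rng.normal(0.0, noise.white_sd, (48, n))
        data = data + sps.lfilter([1.0], [1.0, -noise.ar1_coef], e, axis=1)
    for osc in noise.oscillations:
        if osc.amplitude == 0:
            continue
        phase = rng.uniform(0, 2 * np.pi, 48) if osc.random_phase else np.zeros(48)
        data = data + osc.amplitude * np.sin(2 * np.pi * osc.freq_hz * t[None, :] + phase[:, None])
    if noise.drift_slope_sd > 0:
        slope = rng.normal(0.0, noise.drift_slope_sd, 48)
        data = data + slope[:, None] * t[None, :]
    # motion artifacts last, so preprocessing must genuinely remove them
    art = cfg.artifact
    dur_min = p.total_s / 60.0
    for c in range(48):
        for _ in range(rng.poisson(art.spike_rate_per_min * dur_min)):
            pos = rng.integers(0, n)
            data[c, pos] += rng.normal(0.0, art.spike_amplitude_sd)
        for _ in range(rng.poisson(art.shift_rate_per_min * dur_min)):
            pos = rng.integers(1, n)
            data[c, pos:] += rng.normal(0.0, art.shift_amplitude_sd)
    rec = Recording(
        subject_id=sp.subject_id,
        group=sp.group,
        timepoint=timepoint,
        fs=p.fs,
        channel_ids=tuple(range(1, 49)),
        data=data,
    )
    if cfg.emit_intensity:
        inten, hbr = emit_intensity(data, cfg.preproc.mbll, i0=1.0)
        rec.intensity = inten
        rec.hbr = hbr
        rec.i0 = np.ones((2, 48))
    return rec


def _rng_for(cfg: SimConfig, group: str, subject_idx: int, stream: int) -> np.random.Generator:
    gi = cfg.groups.index(group)
    return np.random.default_rng([int(cfg.seed) % (2**31), gi, subject_idx, stream])


def simulate_recording(cfg: SimConfig, subject_idx: int, group: str,
                       timepoint: str) -> Recording:
    """Single-recording entry point, reproducible from (seed, subject, timepoint)."""
    sp = _draw_subject(cfg, f"{group[:3]}{subject_idx:03d}", group,
                       _rng_for(cfg, group, subject_idx, 0))
    return _render(cfg, sp, timepoint, _rng_for(cfg, group, subject_idx,
                                                1 + TIMEPOINTS.index(timepoint)))


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass
class SubjectTruth:
    subject_id: str
    group: str
    increments: dict
    expected_contrast: dict  # timepoint -> (48,) realized task-minus-baseline contrast
    expected_mean_z: dict  # timepoint -> ground-truth mean Fisher-z over 1128 pairs
    expected_mean_fc: dict  # timepoint -> back-transformed mean r
    delta_mean_fc: float  # post - pre, model-implied, r scale
    delta_measured: float = float("nan")  # pipeline-observable mean-FC change
    u: float = float("nan")  # standardized coupling driver


@dataclass
class CohortTruth:
    subjects: dict  # subject_id -> SubjectTruth
    group_moments: dict  # group -> (mu, sd) of delta_mean_fc
    contrast_factor: float
    contrast_factor_raw: float


@dataclass
class Cohort:
    config: SimConfig
    recordings: list  # Recording, present unless generate_recordings=False
    scales: pd.DataFrame
    truth: CohortTruth


_MOMENT_CACHE: dict[str, tuple[float, float]] = {}


def _truth_moments(cfg: SimConfig, group: str) -> tuple[float, float]:
    """Monte-Carlo population moments of the ground-truth mean-FC change."""
    key = repr((
        group, cfg.activation_amplitude, cfg.fc_communities, cfg.noise, cfg.slow_scale,
        cfg.amplitude_between_sd, cfg.amplitude_session_sd, cfg.paradigm, cfg.hrf,
        cfg.preproc.lowpass_cutoff_hz, cfg.preproc.filter_order, cfg.n_truth_mc,
        tuple(sorted((c.id, c.roi) for c in cfg.montage.channels)),
    ))
    if key in _MOMENT_CACHE:
        return _MOMENT_CACHE[key]
    exp = _expectations(cfg)
    rng = np.random.default_rng([int(cfg.seed) % (2**31) * 0 + 987654321, cfg.groups.index(group)])
    deltas = np.empty(cfg.n_truth_mc)
    for i in range(cfg.n_truth_mc):
        sp = _draw_subject(cfg, "mc", group, rng)
        _, pre = exp.mean_fc(sp.amp["pre"], sp.loadings["pre"])
        _, post = exp.mean_fc(sp.amp["post"], sp.loadings["post"])
        deltas[i] = post - pre
    mom = (float(deltas.mean()), float(deltas.std(ddof=1)))
    _MOMENT_CACHE[key] = mom
    return mom


def _draw_scale(spec: ScaleSpec, group: str, improvement: float,
                rng: np.random.Generator) -> tuple[float, float]:
    base = rng.normal(dict(spec.baseline_mean)[group], dict(spec.baseline_sd)[group])
    if spec.integer:
        base = round(base)
    base = float(np.clip(base, spec.lo, spec.hi))
    post = base - improvement
    if spec.integer:
        post = round(post)
    post = float(np.clip(post, spec.lo, spec.hi))
    return base, post


def _measured_mean_fc(rec: Recording, cfg: SimConfig) -> float:
    """The pipeline-observable grand-mean FC of one rendered recording."""
    from .connectivity import fc_matrix, mean_fc
    from .preprocess import preprocess_recording

    prec, _ = preprocess_recording(rec, cfg.paradigm, cfg.preproc)
    return mean_fc(fc_matrix(prec, cfg.paradigm))


def simulate_cohort(cfg: SimConfig, generate_recordings: bool = True) -> Cohort:
    """Generate the full two-group, two-timepoint cohort.

    Returns recordings (2 per subject), the clinical-scale table (long
    format, one row per subject x timepoint) and the ground-truth record.

    The PSQI improvement is coupled at population correlation
    ``coupling_r`` to the subject's mean-FC change. When recordings are
    rendered, the coupling driver is the *observable* change — the
    generator runs its own preprocessing + task-window Pearson FC on the
    rendered data — standardized within the group cohort, so the
    configured correlation refers to the quantity an analyst actually
    measures (task-window FC estimates carry irreducible sampling noise
    under a 0.1 Hz band and a 60 s window, so the model-implied change
    alone would attenuate any observable correlation far below its
    nominal value). With ``generate_recordings=False`` only scales and
    ground truth are produced and the coupling falls back to the
    model-implied change standardized by its Monte-Carlo moments (used
    by large-n coupling tests).
    """
    exp = _expectations(cfg)
    scale_specs = dict(cfg.scales)
    recordings: list[Recording] = []
    rows = []
    subjects: dict[str, SubjectTruth] = {}
    moments = {g: _truth_moments(cfg, g) for g in cfg.groups}
    rho = cfg.coupling_r
    for group in cfg.groups:
        mu_gt, sd_gt = moments[group]
        sids = [f"{group[:3]}{i:03d}" for i in range(cfg.n_per_group)]
        drivers = np.empty(cfg.n_per_group)
        for i, sid in enumerate(sids):
            sp = _draw_subject(cfg, sid, group, _rng_for(cfg, group, i, 0))
            mz, mfc = {}, {}
            for tp in TIMEPOINTS:
                z, r = exp.mean_fc(sp.amp[tp], sp.loadings[tp])
                mz[tp], mfc[tp] = z, r
            delta_gt = mfc["post"] - mfc["pre"]
            delta_meas = float("nan")
            if generate_recordings:
                recs = {tp: _render(cfg, sp, tp, _rng_for(cfg, group, i, 1 + j))
                        for j, tp in enumerate(TIMEPOINTS)}
                recordings.extend(recs[tp] for tp in TIMEPOINTS)
                delta_meas = (_measured_mean_fc(recs["post"], cfg)
                              - _measured_mean_fc(recs["pre"], cfg))
            subjects[sid] = SubjectTruth(
                subject_id=sid, group=group, increments=sp.increments,
                expected_contrast={tp: exp.expected_contrast(sp.amp[tp])
                                   for tp in TIMEPOINTS},
                expected_mean_z=mz, expected_mean_fc=mfc,
                delta_mean_fc=delta_gt, delta_measured=delta_meas,
            )
            drivers[i] = delta_meas if generate_recordings else delta_gt
        if generate_recordings:
            dsd = drivers.std(ddof=1)
            u_vals = (drivers - drivers.mean()) / dsd if dsd > 0 else np.zeros_like(drivers)
        else:
            u_vals = (drivers - mu_gt) / sd_gt if sd_gt > 0 else np.zeros_like(drivers)
        for i, sid in enumerate(sids):
            u = float(u_vals[i])
            subjects[sid].u = u
            srng = _rng_for(cfg, group, i, 5)
            row_pre = {"subject": sid, "group": group, "timepoint": "pre"}
            row_post = {"subject": sid, "group": group, "timepoint": "post"}
            for name in SCALE_COLUMNS:
                spec = scale_specs.get(name)
                if spec is None:
                    continue
                im = dict(spec.improvement_mean)[group]
                isd = dict(spec.improvement_sd)[group]
                if name == "psqi_total":
                    eps = srng.standard_normal()
                    improvement = im + isd * (rho * u + np.sqrt(1 - rho**2) * eps)
                else:
                    improvement = srng.normal(im, isd)
                b, a = _draw_scale(spec, group, improvement, srng)
                row_pre[name] = b
                row_post[name] = a
            rows.extend([row_pre, row_post])
    scales = pd.DataFrame(rows)
    truth = CohortTruth(
        subjects=subjects,
        group_moments=moments,
        contrast_factor=exp.contrast_factor,
        contrast_factor_raw=exp.contrast_factor_raw,
    )
    return Cohort(config=cfg, recordings=recordings, scales=scales, truth=truth)
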