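"""Signal conditioning for block-design fNIRS recordings.

The fixed pipeline order is: optional intensity->concentration conversion
(modified Beer-Lambert law), motion-artifact detection and repair,
Butterworth low-pass filtering, and baseline "panning" (re-zeroing each
channel on the minimum of the last 10 s of the pre-task rest). Channel
and subject quality gating applies the >= 36 good-channel rule.

Only a low-pass is applied by default; slow offsets are handled by
panning. An optional high-pass exists for sensitivity analyses but
defaults off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, signal

from .paradigm import Paradigm
from .recording import Recording

__all__ = [
    "MBLLParams",
    "PreprocConfig",
    "QualityReport",
    "mbll_convert",
    "emit_intensity",
    "detect_motion",
    "correct_motion",
    "lowpass",
    "lowpass_sos",
    "baseline_pan",
    "assess_quality",
    "subject_valid",
    "preprocess_recording",
]


@dataclass(frozen=True)
class MBLLParams:
    """Modified Beer-Lambert law constants for the 785/825 nm pair.

    Extinction coefficients are in (mmol/L.mm)^-1; literature-typical
    values for HbO2/HbR at these wavelengths. ``dpf`` are differential
    pathlength factors per wavelength. Concentrations are expressed as
    concentration x pathlength (mmol/L.mm), so the source-detector
    distance itself drops out of the inversion.
    """

    wavelengths_nm: tuple[float, float] = (785.0, 825.0)
    # rows: wavelength, cols: (HbO2, HbR)
    extinction: tuple[tuple[float, float], tuple[float, float]] = (
        (0.0735, 0.1104),
        (0.0927, 0.0773),
    )
    dpf: tuple[float, float] = (6.0, 6.0)
    hbr_ratio: float = 1.0 / 3.0  # |HbR| response as a fraction of HbO2, anticorrelated

    def matrix(self) -> np.ndarray:
        e = np.asarray(self.extinction, dtype=float)
        d = np.asarray(self.dpf, dtype=float)[:, None]
        m = e * d
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("singular extinction system (proportional rows)")
        return m


@dataclass(frozen=True)
class PreprocConfig:
    lowpass_cutoff_hz: float = 0.1
    filter_order: int = 4
    zero_phase: bool = True
    highpass_cutoff_hz: float | None = None  # off by default
    baseline_tail_s: float = 10.0
    motion_method: str = "interpolate"  # or "none"
    motion_window_s: float = 2.0
    motion_z_threshold: float = 5.0
    quality_sd_floor: float = 1e-6
    quality_max_artifact_fraction: float = 0.20
    min_good_channels: int = 36
    mbll: MBLLParams = field(default_factory=MBLLParams)

    def validated_for(self, fs: float) -> "PreprocConfig":
        if not 0 < self.lowpass_cutoff_hz < fs / 2:
            raise ValueError("low-pass cutoff must lie in (0, fs/2)")
        if self.min_good_channels < 1:
            raise ValueError("min_good_channels must be >= 1")
        # values above the channel count are allowed: they exclude every
        # subject, which surfaces as a documented empty-cohort error
        return self


@dataclass
class QualityReport:
    """Per-channel signal quality for one recording."""

    channel_ids: tuple[int, ...]
    good: np.ndarray  # boolean, per channel
    scores: np.ndarray  # artifact fraction per channel (lower is better)
    reasons: tuple[tuple[str, ...], ...]
    min_good_channels: int

    @property
    def n_good(self) -> int:
        return int(self.good.sum())

    @property
    def subject_valid(self) -> bool:
        """Gate for a single session; pair two sessions with subject_valid()."""
        return self.n_good >= self.min_good_channels

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "channel_id": self.channel_ids,
                "good": self.good,
                "artifact_fraction": self.scores,
                "reasons": [";".join(r) for r in self.reasons],
            }
        )


def subject_valid(pre: QualityReport, post: QualityReport) -> bool:
    """A subject is analysable only if both sessions pass the gate."""
    return pre.subject_valid and post.subject_valid


# ---------------------------------------------------------------------------
# MBLL
# ---------------------------------------------------------------------------

def mbll_convert(rec: Recording, cfg: PreprocConfig, paradigm: Paradigm | None = None) -> Recording:
    """Convert dual-wavelength intensities to HbO2 (and HbR) concentration.

    Optical density change is -log10(I / I0). I0 is the stored reference
    intensity when the recording carries one (the exact inverse of
    :func:`emit_intensity`); otherwise it is estimated as the mean over
    the first ``baseline_tail_s`` of the recording. The 2x2 extinction
    system is solved per sample.
    """
    if rec.intensity is None:
        raise ValueError("recording has no intensity data")
    inten = np.asarray(rec.intensity, dtype=float)
    if inten.shape[0] != 2:
        raise ValueError("expected two wavelengths")
    if np.any(inten <= 0):
        raise ValueError("intensities must be strictly positive")
    if rec.i0 is not None:
        i0 = np.asarray(rec.i0, dtype=float)[..., None]
    else:
        n0 = max(1, round(cfg.baseline_tail_s * rec.fs))
        i0 = inten[:, :, :n0].mean(axis=2, keepdims=True)
    od = -np.log10(inten / i0)  # (2, nchan, nsamp)
    m_inv = np.linalg.inv(cfg.mbll.matrix())
    conc = np.einsum("cw,wkt->ckt", m_inv, od)  # (2=HbO,HbR, nchan, nsamp)
    out = rec.copy_with(conc[0], mbll="applied")
    out.hbr = conc[1]
    return out


def emit_intensity(
    hbo: np.ndarray, params: MBLLParams, i0: float | np.ndarray = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Forward model: HbO2 (mmol/L.mm) -> dual-wavelength intensities.

    HbR is tied to HbO2 by the fixed anticorrelated ratio. Returns
    (intensity with shape (2, nchan, nsamp), hbr).
    """
    hbo = np.asarray(hbo, dtype=float)
    hbr = -params.hbr_ratio * hbo
    conc = np.stack([hbo, hbr])  # (2, nchan, nsamp)
    od = np.einsum("wc,ckt->wkt", params.matrix(), conc)
    i0 = np.asarray(i0, dtype=float)
    if i0.ndim:
        i0 = i0[..., None]
    return i0 * 10.0 ** (-od), hbr


# ---------------------------------------------------------------------------
# Motion artifacts
# ---------------------------------------------------------------------------

def detect_motion(rec: Recording, cfg: PreprocConfig) -> np.ndarray:
    """Boolean artifact mask (channels x samples).

    A sample is flagged when the moving-window z-score of the first
    difference exceeds the threshold; the centre is a moving median over
    ``motion_window_s`` and the scale a per-channel robust sd
    (1.4826 x MAD of the differences), so that large spikes cannot mask
    themselves by inflating a local standard deviation. Flags are
    dilated by half a window on each side.
    """
    x = rec.data
    win = max(3, round(cfg.motion_window_s * rec.fs)) | 1  # odd
    if x.shape[1] < 2 * win:
        raise ValueError("recording too short for motion detection")
    mask = np.zeros_like(x, dtype=bool)
    if not np.isfinite(cfg.motion_z_threshold):
        return mask
    d = np.diff(x, axis=1)
    center = signal.medfilt2d(d, kernel_size=(1, win))
    mad = np.median(np.abs(d - np.median(d, axis=1, keepdims=True)), axis=1)
    scale = np.maximum(1.4826 * mad, 1e-12)[:, None]
    z = np.abs(d - center) / scale
    hits = z > cfg.motion_z_threshold
    # a spike at sample t produces outlier differences at t-1 and t
    dmask = np.zeros_like(mask)
    dmask[:, :-1] |= hits
    dmask[:, 1:] |= hits
    half = max(1, win // 2)
    structure = np.ones(2 * half + 1, dtype=bool)
    from scipy.ndimage import binary_dilation

    for c in range(x.shape[0]):
        if dmask[c].any():
            mask[c] = binary_dilation(dmask[c], structure=structure)
    return mask


def _masked_runs(m: np.ndarray):
    """(start, stop) index pairs of contiguous True runs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], m, [False])).astype(np.int8)))
    return zip(idx[0::2], idx[1::2])


def correct_motion(rec: Recording, mask: np.ndarray, method: str = "interpolate") -> Recording:
    """Replace flagged spans by cubic interpolation from flanking samples.

    Each contiguous artifact span is bridged by the cubic through the
    two nearest clean samples on either side (all spans solved in one
    batched 4x4 Vandermonde system); spans at a record edge, where two
    anchors per side do not exist, fall back to linear interpolation /
    nearest-value extension. Interpolating a linear trend is exact.
    """
    if method == "none":
        return rec.copy_with(rec.data.copy(), motion="none")
    if method != "interpolate":
        raise ValueError(f"unknown motion correction method {method!r}")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != rec.data.shape:
        raise ValueError("mask shape must match data")
    out = rec.data.copy()
    n = rec.data.shape[1]
    anchors_x, anchors_y, spans = [], [], []
    for c in range(rec.data.shape[0]):
        m = mask[c]
        if not m.any():
            continue
        if m.all():
            raise ValueError(f"channel {rec.channel_ids[c]} fully masked; cannot repair")
        good_idx = np.flatnonzero(~m)
        for start, stop in _masked_runs(m):
            left = good_idx[np.searchsorted(good_idx, start) - 2:
                            np.searchsorted(good_idx, start)]
            right = good_idx[np.searchsorted(good_idx, stop):
                             np.searchsorted(good_idx, stop) + 2]
            span = np.arange(start, stop)
            if left.size == 2 and right.size == 2:
                ax = np.concatenate([left, right])
                anchors_x.append(ax)
                anchors_y.append(out[c, ax])
                spans.append((c, span, ax[0]))
            else:  # record edge
                out[c, span] = np.interp(span, good_idx, out[c, good_idx])
    if anchors_x:
        ax = np.stack(anchors_x).astype(float)
        ay = np.stack(anchors_y)
        x0 = ax[:, :1]
        v = (ax - x0)[..., None] ** np.arange(4)[None, None, :]  # (runs, 4, 4)
        coef = np.linalg.solve(v, ay[..., None])[..., 0]
        for k, (c, span, x_off) in enumerate(spans):
            rel = span - x_off
            out[c, span] = coef[k] @ np.vander(rel, 4, increasing=True).T
    if not np.all(np.isfinite(out)):
        raise ValueError("motion correction produced non-finite samples")
    return rec.copy_with(out, motion="interpolate")


# ---------------------------------------------------------------------------
# Filtering and panning
# ---------------------------------------------------------------------------

def lowpass_sos(cfg: PreprocConfig, fs: float) -> np.ndarray:
    if not 0 < cfg.lowpass_cutoff_hz < fs / 2 * 0.95:
        raise ValueError("unstable design: cutoff too close to Nyquist")
    return signal.butter(cfg.filter_order, cfg.lowpass_cutoff_hz, btype="low", fs=fs, output="sos")


def lowpass(rec: Recording, cfg: PreprocConfig) -> Recording:
    """Butterworth low-pass (0.1 Hz default), zero-phase when configured."""
    sos = lowpass_sos(cfg, rec.fs)
    if cfg.zero_phase:
        y = signal.sosfiltfilt(sos, rec.data, axis=1)
    else:
        y = signal.sosfilt(sos, rec.data, axis=1)
    if cfg.highpass_cutoff_hz:
        hp = signal.butter(
            cfg.filter_order, cfg.highpass_cutoff_hz, btype="high", fs=rec.fs, output="sos"
        )
        y = signal.sosfiltfilt(hp, y, axis=1) if cfg.zero_phase else signal.sosfilt(hp, y, axis=1)
    return rec.copy_with(y, lowpass=cfg.lowpass_cutoff_hz)


def baseline_pan(rec: Recording, paradigm: Paradigm, cfg: PreprocConfig) -> Recording:
    """Subtract the per-channel minimum of the last 10 s of pre-task rest.

    After panning, the minimum of that window is exactly zero for every
    channel; applying the operation twice changes nothing.
    """
    sl = paradigm.pan_slice(cfg.baseline_tail_s)
    if sl.stop <= sl.start or sl.stop > rec.n_samples:
        raise ValueError("empty or out-of-range panning window")
    mins = rec.data[:, sl].min(axis=1, keepdims=True)
    return rec.copy_with(rec.data - mins, panned=True)


# ---------------------------------------------------------------------------
# Quality
# ---------------------------------------------------------------------------

def assess_quality(
    rec: Recording, cfg: PreprocConfig, mask: np.ndarray | None = None
) -> QualityReport:
    """Composite per-channel quality rule.

    A channel is good iff it is finite everywhere, not flat (sd above a
    floor, which catches saturated or disconnected optodes), and its
    motion-artifact fraction is below the configured limit.
    """
    if rec.n_samples == 0:
        raise ValueError("empty recording")
    if mask is None:
        mask = detect_motion(rec, cfg)
    frac = mask.mean(axis=1)
    good = np.ones(rec.n_channels, dtype=bool)
    reasons: list[tuple[str, ...]] = []
    sds = rec.data.std(axis=1)
    finite = np.all(np.isfinite(rec.data), axis=1)
    for c in range(rec.n_channels):
        why = []
        if not finite[c]:
            why.append("non-finite")
        if sds[c] <= cfg.quality_sd_floor:
            why.append("flat")
        if frac[c] >= cfg.quality_max_artifact_fraction:
            why.append("artifact-fraction")
        good[c] = not why
        reasons.append(tuple(why))
    return QualityReport(
        channel_ids=rec.channel_ids,
        good=good,
        scores=frac,
        reasons=tuple(reasons),
        min_good_channels=cfg.min_good_channels,
    )


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def preprocess_recording(
    rec: Recording, paradigm: Paradigm, cfg: PreprocConfig | None = None
) -> tuple[Recording, QualityReport]:
    """Run the fixed pipeline: (mbll?) -> motion -> low-pass -> panning.

    Quality is assessed on the raw (post-MBLL) signal so that repaired
    artifacts still count against a channel's artifact fraction.
    """
    cfg = (cfg or PreprocConfig()).validated_for(rec.fs)
    if rec.intensity is not None and rec.meta.get("mbll") != "applied":
        rec = mbll_convert(rec, cfg, paradigm)
    mask = detect_motion(rec, cfg)
    report = assess_quality(rec, cfg, mask=mask)
    rec = correct_motion(rec, mask, method=cfg.motion_method)
    rec = lowpass(rec, cfg)
    rec = baseline_pan(rec, paradigm, cfg)
    rec.meta["pipeline"] = "mbll?>motion>lowpass>pan"
    return rec, report
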