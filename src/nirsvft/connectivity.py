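"""Task-state functional connectivity (FC) networks.

FC is the Pearson correlation between two channels' HbO2 series over the
60 s task window only. All averaging and inference on correlations runs
on the Fisher z scale (variance stabilisation; a config switch allows
raw-r averaging for sensitivity checks), with results back-transformed
to r for reporting. Bad channels are removed pairwise, shrinking the
test family accordingly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .activation import benjamini_hochberg, paired_t
from .clinical import cohens_d_ci
from .montage import ROI_NAMES, Montage
from .paradigm import Paradigm
from .recording import Recording

__all__ = [
    "FCMatrix",
    "fisher_z",
    "fisher_inv",
    "fc_matrix",
    "roi_fc",
    "mean_fc",
    "cohort_fc",
    "fc_change_tests",
    "correlate_outcome",
]

_Z_CLIP = 0.999999999999


def fisher_z(r) -> np.ndarray:
    return np.arctanh(np.clip(r, -_Z_CLIP, _Z_CLIP))


def fisher_inv(z) -> np.ndarray:
    return np.tanh(z)


@dataclass
class FCMatrix:
    """Symmetric 48x48 task-window Pearson matrix for one recording."""

    subject_id: str
    group: str
    timepoint: str
    r: np.ndarray
    good: np.ndarray  # per-channel boolean mask
    channel_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        r = self.r
        ok = self.good
        if r.shape[0] != r.shape[1]:
            raise ValueError("FC matrix must be square")
        finite = r[np.ix_(ok, ok)]
        if not np.allclose(finite, finite.T, equal_nan=True):
            raise ValueError("FC matrix must be symmetric")


def fc_matrix(
    rec: Recording, paradigm: Paradigm, good: np.ndarray | None = None
) -> FCMatrix:
    """Pearson FC over the task window; unit diagonal for good channels.

    Channels flagged bad, or with zero variance in the window, get NaN
    rows/columns (pairwise deletion downstream).
    """
    window = rec.data[:, paradigm.task_slice]
    if window.shape[1] < 3:
        raise ValueError("task window must contain at least 3 samples")
    n = rec.n_channels
    ok = np.ones(n, dtype=bool) if good is None else np.asarray(good, dtype=bool).copy()
    ok &= window.std(axis=1) > 0
    ok &= np.all(np.isfinite(window), axis=1)
    r = np.full((n, n), np.nan)
    if ok.sum() >= 1:
        sub = np.corrcoef(window[ok])
        sub = np.atleast_2d(sub)
        r[np.ix_(ok, ok)] = sub
    idx = np.where(ok)[0]
    r[idx, idx] = 1.0
    return FCMatrix(
        subject_id=rec.subject_id,
        group=rec.group,
        timepoint=rec.timepoint,
        r=r,
        good=ok,
        channel_ids=rec.channel_ids,
    )


def _pair_mean(values: np.ndarray, use_fisher: bool = True) -> float:
    vals = values[~np.isnan(values)]
    if vals.size == 0:
        return float("nan")
    if use_fisher:
        return float(fisher_inv(np.mean(fisher_z(vals))))
    return float(np.mean(vals))


def roi_fc(fc: FCMatrix, montage: Montage, use_fisher: bool = True) -> pd.DataFrame:
    """9x9 ROI-level FC: back-transformed mean Fisher-z over channel pairs.

    Off-diagonal (A, B): all pairs (a in A, b in B). Diagonal (A, A):
    distinct within-ROI pairs. ROIs with no good channel are missing.
    """
    mat = np.full((9, 9), np.nan)
    roi_idx = {roi: np.array([c - 1 for c in montage.roi_channels(roi)]) for roi in ROI_NAMES}
    for i, a in enumerate(ROI_NAMES):
        for j, b in enumerate(ROI_NAMES):
            if j < i:
                continue
            ia, ib = roi_idx[a], roi_idx[b]
            if i == j:
                pairs = np.array(list(itertools.combinations(ia, 2)))
                vals = fc.r[pairs[:, 0], pairs[:, 1]]
            else:
                vals = fc.r[np.ix_(ia, ib)].ravel()
            mat[i, j] = mat[j, i] = _pair_mean(vals, use_fisher)
    return pd.DataFrame(mat, index=list(ROI_NAMES), columns=list(ROI_NAMES))


def mean_fc(fc: FCMatrix, use_fisher: bool = True) -> float:
    """Grand mean FC over all good off-diagonal unordered channel pairs."""
    iu = np.triu_indices(fc.r.shape[0], k=1)
    vals = fc.r[iu]
    out = _pair_mean(vals, use_fisher)
    if np.isnan(out):
        raise ValueError("no good channel pair")
    return out


def cohort_fc(recordings, paradigm: Paradigm, quality: dict | None = None) -> list[FCMatrix]:
    """FC matrices for a set of (preprocessed) recordings."""
    out = []
    for rec in recordings:
        good = None
        if quality is not None:
            rep = quality.get((rec.subject_id, rec.timepoint))
            if rep is not None:
                good = rep.good
        out.append(fc_matrix(rec, paradigm, good=good))
    return out


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

def _paired_z(fcs: list[FCMatrix], group: str):
    """Per-subject (pre, post) Fisher-z stacks for one group."""
    by_subject: dict[str, dict[str, FCMatrix]] = {}
    for fc in fcs:
        if fc.group == group:
            by_subject.setdefault(fc.subject_id, {})[fc.timepoint] = fc
    pairs = [(s, d["pre"], d["post"]) for s, d in sorted(by_subject.items())
             if "pre" in d and "post" in d]
    return pairs


def _roi_pair_values(fc: FCMatrix, montage: Montage) -> dict[tuple[str, str], float]:
    table = roi_fc(fc, montage)
    out = {}
    for a, b in montage.roi_pairs(include_self=True):
        out[(a, b)] = table.loc[a, b]
    return out


def fc_change_tests(
    fcs: list[FCMatrix],
    montage: Montage,
    level: str = "roi-pair",
    alpha: float = 0.05,
    groups: tuple[str, str] = ("intervention", "control"),
) -> pd.DataFrame:
    """Pre/post and between-group FC statistics on the Fisher-z scale.

    ``level``: 'pair' (1128 channel pairs), 'roi-pair' (45 ROI pairs,
    including within-ROI entries), or 'mean' (single grand-mean test,
    uncorrected). Within-group: paired t on z_post - z_pre. Between
    groups: two-sample t on the change with Cohen's d. BH-FDR is
    applied within the family at 'pair' and 'roi-pair' level; missing
    pairs shrink the family size.
    """
    if level == "pair":
        n_ch = fcs[0].r.shape[0]
        iu = np.triu_indices(n_ch, k=1)
        labels = [f"ch{fcs[0].channel_ids[i]}-ch{fcs[0].channel_ids[j]}"
                  for i, j in zip(*iu)]
        meta = [(fcs[0].channel_ids[i], fcs[0].channel_ids[j]) for i, j in zip(*iu)]

        def values(fc: FCMatrix) -> np.ndarray:
            return fisher_z(fc.r[iu])

    elif level == "roi-pair":
        pair_names = list(montage.roi_pairs(include_self=True))
        labels = [f"{a}-{b}" for a, b in pair_names]
        meta = pair_names

        def values(fc: FCMatrix) -> np.ndarray:
            vals = _roi_pair_values(fc, montage)
            return fisher_z(np.array([vals[p] for p in pair_names]))

    elif level == "mean":
        labels = ["mean_fc"]
        meta = [("all", "all")]

        def values(fc: FCMatrix) -> np.ndarray:
            return fisher_z(np.array([mean_fc(fc)]))

    else:
        raise ValueError(f"unknown level {level!r}")

    deltas: dict[str, np.ndarray] = {}
    rows = []
    for g in groups:
        pairs = _paired_z(fcs, g)
        if len(pairs) < 2:
            raise ValueError(f"need >= 2 paired subjects in group {g}")
        pre = np.stack([values(p[1]) for p in pairs])
        post = np.stack([values(p[2]) for p in pairs])
        deltas[g] = post - pre
    for k, label in enumerate(labels):
        row: dict = {"edge": label, "a": meta[k][0], "b": meta[k][1]}
        for g in groups:
            d = deltas[g][:, k]
            d = d[~np.isnan(d)]
            tag = "g1" if g == groups[0] else "g2"
            if d.size < 2:
                row.update({f"{tag}_n": d.size, f"{tag}_t": np.nan, f"{tag}_p": np.nan,
                            f"{tag}_dz": np.nan, f"{tag}_dr": np.nan})
                continue
            t, p, _ = paired_t(d)
            row.update({f"{tag}_n": d.size, f"{tag}_t": float(t), f"{tag}_p": float(p),
                        f"{tag}_dz": float(d.mean())})
        d1 = deltas[groups[0]][:, k]
        d2 = deltas[groups[1]][:, k]
        d1, d2 = d1[~np.isnan(d1)], d2[~np.isnan(d2)]
        if d1.size >= 2 and d2.size >= 2:
            sp2 = ((d1.size - 1) * d1.var(ddof=1) + (d2.size - 1) * d2.var(ddof=1)) / (
                d1.size + d2.size - 2)
            if sp2 > 0:
                t_b = (d1.mean() - d2.mean()) / np.sqrt(sp2 * (1 / d1.size + 1 / d2.size))
                p_b = 2 * stats.t.sf(abs(t_b), d1.size + d2.size - 2)
                d_cohen = (d1.mean() - d2.mean()) / np.sqrt(sp2)
                ci = cohens_d_ci(d_cohen, d1.size, d2.size)
            else:
                t_b, p_b = 0.0, 1.0
                d_cohen, ci = 0.0, (0.0, 0.0)
            row.update({"between_t": float(t_b), "between_p": float(p_b),
                        "between_d": float(d_cohen),
                        "between_d_ci_low": ci[0], "between_d_ci_high": ci[1]})
        rows.append(row)
    out = pd.DataFrame(rows)
    if level != "mean":
        for col in ("g1_p", "g2_p", "between_p"):
            out[col.replace("_p", "_q")] = benjamini_hochberg(out[col].to_numpy())
        out["g1_significant"] = (out["g1_q"] < alpha).fillna(False)
        out["g2_significant"] = (out["g2_q"] < alpha).fillna(False)
        out["between_significant"] = (out["between_q"] < alpha).fillna(False)
    return out


def correlate_outcome(delta_fc, delta_scale) -> dict:
    """Brain-behaviour Pearson correlation with t-based p and Fisher CI.

    t = r sqrt((n-2)/(1-r^2)), two-sided; the 95% CI comes from the
    Fisher z interval z +/- 1.96/sqrt(n-3).
    """
    x = np.asarray(delta_fc, dtype=float)
    y = np.asarray(delta_scale, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be paired 1-D vectors")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in a correlate")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = float(2 * stats.t.sf(abs(t), n - 2))
    if n > 3:
        zc = stats.norm.ppf(0.975) / np.sqrt(n - 3)
        ci = (float(fisher_inv(fisher_z(r) - zc)), float(fisher_inv(fisher_z(r) + zc)))
    else:
        ci = (float("nan"), float("nan"))
    return {"r": r, "p": p, "n": n, "ci": ci}
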