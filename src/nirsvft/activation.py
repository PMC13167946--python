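"""Block-design task activation statistics.

Per subject, activation is the task-window mean minus the pre-task-rest
mean of the preprocessed HbO2 signal ("contrast"), per channel and
averaged over good channels per ROI. Group inference follows the trial:
paired t-tests across subjects (baseline vs task, or pre vs post), with
Benjamini-Hochberg FDR over the 48-channel family; ROI tables report
raw p (q alongside), with the normality-gated test choice and Cohen's d
for the between-group change comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clinical import between_group_change, paired_change
from .montage import ROI_NAMES, Montage
from .paradigm import Paradigm
from .preprocess import QualityReport
from .recording import Recording

__all__ = [
    "block_contrast",
    "cohort_contrasts",
    "benjamini_hochberg",
    "paired_t",
    "channel_activation_tests",
    "roi_tests",
]


def block_contrast(
    rec: Recording, paradigm: Paradigm, good: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-channel (baseline_mean, task_mean, contrast) for one recording.

    Bad channels yield NaN (missing), never zero.
    """
    if paradigm.task_offset > rec.n_samples:
        raise ValueError("paradigm windows exceed recording length")
    base = rec.data[:, paradigm.baseline_slice].mean(axis=1)
    task = rec.data[:, paradigm.task_slice].mean(axis=1)
    out = pd.DataFrame(
        {
            "channel_id": rec.channel_ids,
            "baseline_mean": base,
            "task_mean": task,
            "contrast": task - base,
        }
    )
    if good is not None:
        bad = ~np.asarray(good, dtype=bool)
        out.loc[bad, ["baseline_mean", "task_mean", "contrast"]] = np.nan
    out.insert(0, "timepoint", rec.timepoint)
    out.insert(0, "group", rec.group)
    out.insert(0, "subject", rec.subject_id)
    return out


def cohort_contrasts(
    recordings, paradigm: Paradigm, quality: dict | None = None
) -> pd.DataFrame:
    """Stack per-recording contrasts into one long table.

    ``quality`` optionally maps (subject, timepoint) -> QualityReport;
    bad channels become missing values.
    """
    frames = []
    for rec in recordings:
        good = None
        if quality is not None:
            rep = quality.get((rec.subject_id, rec.timepoint))
            if isinstance(rep, QualityReport):
                good = rep.good
        frames.append(block_contrast(rec, paradigm, good=good))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def benjamini_hochberg(p, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( m * p_(j) / j ), mapped back to input order
    and clipped to [0, 1]. NaN entries are passed through and do not
    count toward the family size.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    k = pv.size
    if k == 0:
        return out
    m = k if m is None else int(m)
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, k + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    qv = np.empty(k)
    qv[order] = q
    out[ok] = qv
    return out


def paired_t(diff: np.ndarray, axis: int = -1) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized paired t on difference scores: t = mean/ (sd/sqrt(n)).

    Degenerate all-zero differences return t = 0, p = 1 by convention
    (no evidence against the null, rather than 0/0).
    """
    diff = np.asarray(diff, dtype=float)
    n = diff.shape[axis]
    if n < 2:
        raise ValueError("need at least 2 paired observations")
    mean = diff.mean(axis=axis)
    sd = diff.std(axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        t = np.where(sd == 0, np.where(mean == 0, 0.0, np.sign(mean) * np.inf), t)
    p = 2 * stats.t.sf(np.abs(t), df=n - 1)
    return np.asarray(t), np.asarray(p), np.full(np.shape(t), n - 1)


def _pivot_changes(contrasts: pd.DataFrame, group: str) -> pd.DataFrame:
    """subjects x channels table of post-minus-pre contrast changes."""
    sub = contrasts[contrasts["group"] == group]
    wide = sub.pivot_table(
        index="subject", columns=["timepoint", "channel_id"], values="contrast",
        dropna=False,
    )
    pre = wide["pre"]
    post = wide["post"]
    return post - pre


def channel_activation_tests(
    contrasts: pd.DataFrame,
    group: str,
    mode: str = "pre_vs_post",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """48 paired t-tests across subjects with BH-FDR within the family.

    ``mode='pre_vs_post'`` tests the change in task contrast between
    sessions; ``mode='baseline_vs_task'`` tests, per channel at a given
    timepoint encoded in the input, whether the contrast differs from
    zero (the baseline-vs-task activation map). Channels missing for
    every subject are flagged and excluded from the family size m.
    """
    if mode == "pre_vs_post":
        diffs = _pivot_changes(contrasts, group)
    elif mode == "baseline_vs_task":
        sub = contrasts[contrasts["group"] == group]
        diffs = sub.pivot_table(index="subject", columns="channel_id", values="contrast",
                                dropna=False)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for ch in sorted(diffs.columns):
        d = diffs[ch].to_numpy(dtype=float)
        d = d[~np.isnan(d)]
        if d.size < 2:
            rows.append({"channel_id": ch, "n": d.size, "t": np.nan, "df": np.nan,
                         "p": np.nan, "mean_change": np.nan, "excluded": True})
            continue
        t, p, df = paired_t(d)
        rows.append({"channel_id": ch, "n": d.size, "t": float(t), "df": float(df),
                     "p": float(p), "mean_change": float(d.mean()), "excluded": False})
    out = pd.DataFrame(rows)
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    out["significant"] = out["q"] < alpha
    out["significant"] = out["significant"].fillna(False)
    return out


def roi_tests(
    contrasts: pd.DataFrame,
    montage: Montage,
    alpha: float = 0.05,
    groups: tuple[str, str] = ("intervention", "control"),
) -> pd.DataFrame:
    """Per-ROI activation table (within-group change + between-group test).

    ROI contrast is the arithmetic mean of good member-channel contrasts
    per subject. Within each group, pre vs post is a normality-gated
    paired test; between groups, the change scores are compared with an
    independent test and Cohen's d. Raw p is primary; q over the 9 ROIs
    is reported alongside.
    """
    work = contrasts.copy()
    work["roi"] = work["channel_id"].map({c: montage.roi_of(c) for c in montage.channel_ids})
    roi_means = (
        work.groupby(["subject", "group", "timepoint", "roi"], sort=False)["contrast"]
        .mean()
        .reset_index()
    )
    rows = []
    changes: dict[str, dict[str, np.ndarray]] = {g: {} for g in groups}
    for roi in ROI_NAMES:
        row: dict = {"roi": roi}
        for g in groups:
            sub = roi_means[(roi_means["roi"] == roi) & (roi_means["group"] == g)]
            wide = sub.pivot_table(index="subject", columns="timepoint", values="contrast")
            if wide.empty or "pre" not in wide or "post" not in wide:
                raise ValueError(f"no paired data for ROI {roi} in group {g}")
            paired = wide.dropna()
            pre = paired["pre"].to_numpy()
            post = paired["post"].to_numpy()
            res = paired_change(pre, post)
            changes[g][roi] = post - pre
            tag = "g1" if g == groups[0] else "g2"
            row.update({
                f"{tag}_n": pre.size,
                f"{tag}_baseline": pre.mean(),
                f"{tag}_week4": post.mean(),
                f"{tag}_change": res.mean_change,
                f"{tag}_ci_low": res.ci[0],
                f"{tag}_ci_high": res.ci[1],
                f"{tag}_p": res.p,
                f"{tag}_test": res.test,
            })
        bg = between_group_change(changes[groups[0]][roi], changes[groups[1]][roi])
        row.update({
            "between_stat": bg.statistic,
            "between_p": bg.p,
            "between_test": bg.test,
            "effect_size": bg.effect_size,
            "effect_ci_low": bg.effect_ci[0],
            "effect_ci_high": bg.effect_ci[1],
        })
        rows.append(row)
    out = pd.DataFrame(rows)
    for col in ("g1_p", "g2_p", "between_p"):
        out[col.replace("_p", "_q")] = benjamini_hochberg(out[col].to_numpy())
    out["g1_significant"] = out["g1_p"] < alpha
    out["g2_significant"] = out["g2_p"] < alpha
    return out
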