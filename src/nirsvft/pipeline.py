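"""End-to-end orchestration: simulate -> preprocess -> analyse -> report.

Each stage writes its artifacts as plain files under the output
directory, so stages are independently inspectable and resumable, and a
rerun with the same configuration is bit-identical. All randomness
flows from the single run seed through named substreams.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .activation import channel_activation_tests, cohort_contrasts, roi_tests
from .clinical import between_group_change, paired_change
from .connectivity import cohort_fc, correlate_outcome, fc_change_tests, mean_fc
from .io import read_cohort_csv, read_recording_tsv
from .montage import default_montage
from .paradigm import Paradigm
from .preprocess import PreprocConfig, preprocess_recording, subject_valid
from .recording import GROUPS
from .synth import SCALE_COLUMNS, SimConfig, default_sim_config, simulate_cohort

__all__ = ["RunConfig", "PipelineError", "run_all", "clinical_tables", "load_recordings"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    input_dir: Path | None = None  # exactly one input mode: files | simulate
    sim: SimConfig | None = None
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    paradigm: Paradigm = field(default_factory=Paradigm)
    n_per_group: int = 32

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.input_dir is not None and self.sim is not None:
            raise ValueError("choose one input mode: files or simulate")


def load_recordings(input_dir: Path) -> list:
    recs = sorted(Path(input_dir).glob("*_pre.tsv")) + sorted(Path(input_dir).glob("*_post.tsv"))
    if not recs:
        raise PipelineError("load", f"no recordings found in {input_dir}")
    return [read_recording_tsv(p) for p in recs]


def clinical_tables(scales: pd.DataFrame, groups=GROUPS) -> dict[str, pd.DataFrame]:
    """Baseline comparison and pre/post results for every scale column."""
    scale_cols = [c for c in SCALE_COLUMNS if c in scales.columns]
    base_rows, res_rows = [], []

    def safe_between(a, b):
        """Degenerate integer scales (zero pooled variance) yield NaN rows."""
        try:
            return between_group_change(a, b)
        except ValueError:
            nan = float("nan")
            from .clinical import BetweenResult

            return BetweenResult(len(a), len(b), float(np.mean(a) - np.mean(b)),
                                 "independent-t", nan, nan, nan, (nan, nan))

    for col in scale_cols:
        wide = scales.pivot_table(index=["subject", "group"], columns="timepoint", values=col)
        wide = wide.reset_index()
        g1 = wide[wide["group"] == groups[0]]
        g2 = wide[wide["group"] == groups[1]]
        bg_base = safe_between(g1["pre"].to_numpy(), g2["pre"].to_numpy())
        base_rows.append({
            "scale": col,
            f"{groups[0]}_mean": g1["pre"].mean(), f"{groups[0]}_sd": g1["pre"].std(ddof=1),
            f"{groups[1]}_mean": g2["pre"].mean(), f"{groups[1]}_sd": g2["pre"].std(ddof=1),
            "stat": bg_base.statistic, "p": bg_base.p, "test": bg_base.test,
        })
        row: dict = {"scale": col}
        changes = {}
        for g, frame in ((groups[0], g1), (groups[1], g2)):
            res = paired_change(frame["pre"].to_numpy(), frame["post"].to_numpy())
            changes[g] = frame["post"].to_numpy() - frame["pre"].to_numpy()
            row.update({
                f"{g}_baseline_mean": frame["pre"].mean(),
                f"{g}_baseline_sd": frame["pre"].std(ddof=1),
                f"{g}_week4_mean": frame["post"].mean(),
                f"{g}_week4_sd": frame["post"].std(ddof=1),
                f"{g}_change": res.mean_change,
                f"{g}_ci_low": res.ci[0], f"{g}_ci_high": res.ci[1],
                f"{g}_within_p": res.p, f"{g}_test": res.test,
            })
        bg = safe_between(changes[groups[0]], changes[groups[1]])
        row.update({
            "between_stat": bg.statistic, "between_p": bg.p, "between_test": bg.test,
            "effect_size": bg.effect_size,
            "effect_ci_low": bg.effect_ci[0], "effect_ci_high": bg.effect_ci[1],
        })
        res_rows.append(row)
    return {"baseline": pd.DataFrame(base_rows), "results": pd.DataFrame(res_rows)}


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_all(cfg: RunConfig) -> dict:
    """Run the whole pipeline; returns the report bundle as DataFrames.

    Artifacts written under out_dir: quality.tsv, channel t-maps and the
    ROI activation table, per-subject FC matrices, ROI-pair and
    channel-pair edge tables, the grand-mean FC comparison, clinical
    tables, the brain-behaviour correlation report, and provenance.json.
    """
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    # ---- stage: input ---------------------------------------------------
    if cfg.input_dir is not None:
        recordings = load_recordings(cfg.input_dir)
        scales = read_cohort_csv(Path(cfg.input_dir) / "cohort.csv")
        sim = None
        montage = default_montage()
    else:
        sim = cfg.sim or default_sim_config(seed=cfg.seed, n_per_group=cfg.n_per_group,
                                            preproc=cfg.preproc)
        try:
            cohort = simulate_cohort(sim)
        except Exception as e:  # pragma: no cover - config errors
            raise PipelineError("simulate", str(e)) from e
        recordings = cohort.recordings
        scales = cohort.scales
        montage = sim.montage
    paradigm = sim.paradigm if sim is not None else cfg.paradigm
    # ---- stage: preprocess ---------------------------------------------
    try:
        processed, quality = [], {}
        for rec in recordings:
            prec, rep = preprocess_recording(rec, paradigm, cfg.preproc)
            processed.append(prec)
            quality[(rec.subject_id, rec.timepoint)] = rep
    except Exception as e:
        raise PipelineError("preprocess", str(e)) from e
    qrows = []
    for (sid, tp), rep in sorted(quality.items()):
        qrows.append({"subject": sid, "timepoint": tp, "n_good": rep.n_good,
                      "session_valid": rep.subject_valid})
    qframe = pd.DataFrame(qrows)
    _write(qframe, out / "quality.tsv")
    valid_subjects = set()
    for sid in {r.subject_id for r in processed}:
        pre = quality.get((sid, "pre"))
        post = quality.get((sid, "post"))
        if pre is not None and post is not None and subject_valid(pre, post):
            valid_subjects.add(sid)
    if not valid_subjects:
        raise PipelineError("quality", "empty cohort: no subject has enough good channels "
                                       "at both timepoints")
    kept = [r for r in processed if r.subject_id in valid_subjects]
    # ---- stage: activation ----------------------------------------------
    try:
        contrasts = cohort_contrasts(kept, paradigm, quality=quality)
        _write(contrasts, out / "contrasts.tsv")
        roi_map = {c: montage.roi_of(c) for c in montage.channel_ids}
        for g in GROUPS:
            if (contrasts["group"] == g).any():
                tmap = channel_activation_tests(contrasts, g, mode="pre_vs_post")
                tmap.insert(1, "roi", tmap["channel_id"].map(roi_map))
                _write(tmap, out / f"tmap_{g}.tsv")
        roi_table = roi_tests(contrasts, montage)
        _write(roi_table, out / "roi_activation.tsv")
    except Exception as e:
        raise PipelineError("activation", str(e)) from e
    # ---- stage: connectivity --------------------------------------------
    try:
        fcs = cohort_fc(kept, paradigm, quality=quality)
        fc_dir = out / "fc"
        fc_dir.mkdir(exist_ok=True)
        for fc in fcs:
            np.savetxt(fc_dir / f"{fc.subject_id}_{fc.timepoint}.tsv", fc.r,
                       delimiter="\t", fmt="%.6g")
        roi_pair = fc_change_tests(fcs, montage, level="roi-pair")
        _write(roi_pair, out / "fc_roi_pairs.tsv")
        edges = fc_change_tests(fcs, montage, level="pair")
        _write(edges, out / "fc_edges.tsv")
        mean_cmp = fc_change_tests(fcs, montage, level="mean")
        _write(mean_cmp, out / "fc_mean.tsv")
    except Exception as e:
        raise PipelineError("connectivity", str(e)) from e
    # ---- stage: clinical -------------------------------------------------
    try:
        tables = clinical_tables(scales[scales["subject"].isin(
            {r.subject_id for r in recordings})])
        _write(tables["baseline"], out / "scales_baseline.tsv")
        _write(tables["results"], out / "scales_results.tsv")
    except Exception as e:
        raise PipelineError("clinical", str(e)) from e
    # ---- stage: report ---------------------------------------------------
    try:
        mean_by = {}
        for fc in fcs:
            mean_by.setdefault(fc.subject_id, {})[fc.timepoint] = mean_fc(fc)
        psqi = scales.pivot_table(index=["subject", "group"], columns="timepoint",
                                  values="psqi_total").reset_index()
        corr_rows = []
        for g in GROUPS:
            sub = psqi[(psqi["group"] == g) & psqi["subject"].isin(valid_subjects)]
            dfc, dscale = [], []
            for _, row in sub.iterrows():
                m = mean_by.get(row["subject"])
                if m and "pre" in m and "post" in m:
                    dfc.append(m["post"] - m["pre"])
                    dscale.append(row["pre"] - row["post"])  # improvement
            if len(dfc) >= 3:
                res = correlate_outcome(np.array(dfc), np.array(dscale))
                corr_rows.append({"group": g, "n": res["n"], "r": res["r"], "p": res["p"],
                                  "ci_low": res["ci"][0], "ci_high": res["ci"][1],
                                  "mean_delta_fc": float(np.mean(dfc)),
                                  "sd_delta_fc": float(np.std(dfc, ddof=1))})
        corr = pd.DataFrame(corr_rows)
        _write(corr, out / "fc_psqi_correlation.tsv")
    except Exception as e:
        raise PipelineError("report", str(e)) from e
    # ---- provenance ------------------------------------------------------
    cfg_repr = repr((cfg.seed, cfg.n_per_group, cfg.preproc, sim))
    provenance = {
        "package": "nirsvft",
        "version": __version__,
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(cfg_repr.encode()).hexdigest(),
        "n_recordings": len(recordings),
        "n_valid_subjects": len(valid_subjects),
        "numpy": np.__version__,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")
    return {
        "quality": qframe,
        "contrasts": contrasts,
        "roi_activation": roi_table,
        "fc_roi_pairs": roi_pair,
        "fc_edges": edges,
        "fc_mean": mean_cmp,
        "scales_baseline": tables["baseline"],
        "scales_results": tables["results"],
        "correlation": corr,
        "provenance": provenance,
    }
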