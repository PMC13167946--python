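import numpy as np
import pytest
from hypothesis import given, strategies as st

from nirsvft import Paradigm
from nirsvft.connectivity import (
    FCMatrix,
    correlate_outcome,
    fc_change_tests,
    fc_matrix,
    fisher_inv,
    fisher_z,
    mean_fc,
    roi_fc,
)
from nirsvft.recording import Recording


def make_rec(data, subject="s0", group="intervention", timepoint="pre", fs=5.0):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    return Recording(subject_id=subject, group=group, timepoint=timepoint,
                     fs=fs, channel_ids=tuple(range(1, data.shape[0] + 1)),
                     data=data)


def make_fc(r, good=None, subject="s0", group="intervention", timepoint="pre"):
    r = np.asarray(r, dtype=float)
    good = np.ones(r.shape[0], dtype=bool) if good is None else good
    return FCMatrix(subject_id=subject, group=group, timepoint=timepoint,
                    r=r, good=good, channel_ids=tuple(range(1, r.shape[0] + 1)))


# ---------------------------------------------------------------------------
# fc_matrix
# ---------------------------------------------------------------------------

def test_duplicated_and_negated_channels(paradigm):
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, 700)
    data = np.stack([x, x.copy(), -x])
    fc = fc_matrix(make_rec(data), paradigm)
    assert fc.r[0, 1] == pytest.approx(1.0)
    assert fc.r[0, 2] == pytest.approx(-1.0)
    assert np.allclose(np.diag(fc.r), 1.0)


def test_three_sample_toy_window():
    # task window of exactly 3 samples at 1 Hz
    p = Paradigm(pre_rest_s=1.0, task_block_s=1.0, n_blocks=3, post_rest_s=1.0, fs=1.0)
    data = np.zeros((2, p.n_samples))
    data[0, p.task_slice] = [1.0, 2.0, 3.0]
    data[1, p.task_slice] = [1.0, 2.0, 4.0]
    fc = fc_matrix(make_rec(data, fs=1.0), p)
    assert fc.r[0, 1] == pytest.approx(0.9820, abs=1e-4)


def test_zero_variance_channel_is_flagged_missing(paradigm):
    rng = np.random.default_rng(1)
    data = rng.normal(0, 1, (3, 700))
    data[1] = 4.2
    fc = fc_matrix(make_rec(data), paradigm)
    assert not fc.good[1]
    assert np.isnan(fc.r[1, 0]) and np.isnan(fc.r[0, 1])
    assert np.isfinite(fc.r[0, 2])


def test_short_window_is_rejected():
    p = Paradigm(pre_rest_s=1.0, task_block_s=1.0, n_blocks=1, post_rest_s=1.0, fs=1.0)
    with pytest.raises(ValueError, match="3 samples"):
        fc_matrix(make_rec(np.zeros((2, p.n_samples)), fs=1.0), p)


def test_simulated_fc_matrices_are_symmetric_and_bounded(small_cohort, paradigm):
    from nirsvft.preprocess import preprocess_recording

    for rec in small_cohort.recordings[:4]:
        prec, _ = preprocess_recording(rec, paradigm)
        fc = fc_matrix(prec, paradigm)
        assert np.allclose(fc.r, fc.r.T, equal_nan=True)
        ok = ~np.isnan(fc.r)
        assert np.all(np.abs(fc.r[ok]) <= 1.0 + 1e-12)
        assert np.allclose(np.diag(fc.r)[fc.good], 1.0)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def test_roi_fc_trivial_values(montage):
    r = np.zeros((48, 48))
    np.fill_diagonal(r, 1.0)
    table = roi_fc(make_fc(r), montage)
    off = table.to_numpy()
    assert np.allclose(off, np.where(np.eye(9), off, 0.0))

    c = 0.37
    r = np.full((48, 48), c)
    np.fill_diagonal(r, 1.0)
    table = roi_fc(make_fc(r), montage)
    assert np.allclose(table.to_numpy(), c)


def test_roi_fc_fisher_mean_closed_form(montage):
    # exactly two good inter-ROI pairs with r = 0.3 and 0.5
    r = np.full((48, 48), np.nan)
    np.fill_diagonal(r, 1.0)
    good = np.zeros(48, dtype=bool)
    a1, a2 = sorted(montage.rois["rSFC"])[:2]
    b1 = sorted(montage.rois["lSFC"])[0]
    good[[a1 - 1, a2 - 1, b1 - 1]] = True
    r[a1 - 1, b1 - 1] = r[b1 - 1, a1 - 1] = 0.3
    r[a2 - 1, b1 - 1] = r[b1 - 1, a2 - 1] = 0.5
    r[a1 - 1, a2 - 1] = r[a2 - 1, a1 - 1] = 0.0
    table = roi_fc(make_fc(r, good=good), montage)
    expected = np.tanh((np.arctanh(0.3) + np.arctanh(0.5)) / 2)
    assert table.loc["rSFC", "lSFC"] == pytest.approx(expected, abs=1e-4)
    assert expected == pytest.approx(0.4048, abs=1e-4)


def test_mean_fc_trivial_and_toy_values():
    eye = np.eye(3)
    assert mean_fc(make_fc(eye)) == pytest.approx(0.0)

    r = np.full((3, 3), 0.5)
    np.fill_diagonal(r, 1.0)
    assert mean_fc(make_fc(r)) == pytest.approx(0.5, abs=1e-12)

    r = np.eye(3)
    r[0, 1] = r[1, 0] = 0.3
    r[0, 2] = r[2, 0] = 0.5
    r[1, 2] = r[2, 1] = 0.4
    expected = np.tanh(np.mean(np.arctanh([0.3, 0.5, 0.4])))
    assert mean_fc(make_fc(r)) == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(0.4028, abs=1e-3)


def test_mean_fc_without_good_pairs_is_an_error():
    r = np.full((3, 3), np.nan)
    with pytest.raises(ValueError):
        mean_fc(make_fc(r, good=np.zeros(3, dtype=bool)))


@given(st.floats(-0.999, 0.999))
def test_fisher_transform_round_trip(r):
    assert fisher_inv(fisher_z(r)) == pytest.approx(r, abs=1e-12)


def test_fc_matrix_matches_bruteforce_pearson(paradigm):
    """Independent oracle: per-pair sum-formula Pearson on random data."""
    p = Paradigm(pre_rest_s=1.0, task_block_s=50.0, n_blocks=1, post_rest_s=1.0, fs=1.0)
    rng = np.random.default_rng(3)
    for _ in range(20):
        data = rng.normal(0, 1, (5, p.n_samples))
        fc = fc_matrix(make_rec(data, fs=1.0), p)
        win = data[:, p.task_slice]
        for i in range(5):
            for j in range(i + 1, 5):
                x, y = win[i], win[j]
                num = ((x - x.mean()) * (y - y.mean())).sum()
                den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
                assert abs(fc.r[i, j] - num / den) < 1e-10


# ---------------------------------------------------------------------------
# change statistics
# ---------------------------------------------------------------------------

def _paired_fcs(rng, n_subjects=3, delta=0.0):
    out = []
    for g in ("intervention", "control"):
        for s in range(n_subjects):
            base = np.clip(rng.normal(0.3, 0.05, (48, 48)), -0.9, 0.9)
            base = (base + base.T) / 2
            np.fill_diagonal(base, 1.0)
            out.append(make_fc(base, subject=f"{g[:1]}{s}", group=g, timepoint="pre"))
            if delta == 0:
                post = base.copy()
            else:
                post = np.tanh(np.arctanh(np.clip(base, -0.99, 0.99)) + delta)
            np.fill_diagonal(post, 1.0)
            out.append(make_fc(post, subject=f"{g[:1]}{s}", group=g, timepoint="post"))
    return out


def test_identical_pre_post_fc_gives_null_tests(montage):
    fcs = _paired_fcs(np.random.default_rng(4), delta=0.0)
    out = fc_change_tests(fcs, montage, level="roi-pair")
    assert np.all(out["g1_t"] == 0.0)
    assert np.all(out["g1_q"] == 1.0)
    assert len(out) == 45
    out_mean = fc_change_tests(fcs, montage, level="mean")
    assert out_mean["g1_t"].iloc[0] == 0.0


def test_pair_level_family_size(montage):
    fcs = _paired_fcs(np.random.default_rng(5), delta=0.1)
    out = fc_change_tests(fcs, montage, level="pair")
    assert len(out) == 48 * 47 // 2


def test_seeded_community_increment_is_localised(montage):
    """ROI pairs flagged significant after FDR lie inside the seeded
    lSFC+lDLPFC+mPFC+rDLPFC community (plus a small leak allowance)."""
    rng = np.random.default_rng(6)
    comm = set()
    for roi in ("lSFC", "lDLPFC", "mPFC", "rDLPFC"):
        comm |= montage.rois[roi]
    idx = np.array(sorted(comm)) - 1
    fcs = []
    n = 30
    for g in ("intervention", "control"):
        for s in range(n):
            base = 0.3 + rng.normal(0, 0.02)
            pre_r = np.full((48, 48), base)
            np.fill_diagonal(pre_r, 1.0)
            noise = rng.normal(0, 0.05, (48, 48))
            noise = (noise + noise.T) / 2
            pre = np.clip(pre_r + noise, -0.95, 0.95)
            np.fill_diagonal(pre, 1.0)
            post = pre.copy()
            if g == "intervention":
                z = np.arctanh(np.clip(post[np.ix_(idx, idx)], -0.99, 0.99))
                post[np.ix_(idx, idx)] = np.tanh(z + 0.15)
            noise2 = rng.normal(0, 0.05, (48, 48))
            noise2 = (noise2 + noise2.T) / 2
            post = np.clip(post + noise2, -0.95, 0.95)
            np.fill_diagonal(post, 1.0)
            fcs.append(make_fc(pre, subject=f"{g[:1]}{s}", group=g, timepoint="pre"))
            fcs.append(make_fc(post, subject=f"{g[:1]}{s}", group=g, timepoint="post"))
    out = fc_change_tests(fcs, montage, level="roi-pair")
    seeded = {"lSFC", "lDLPFC", "mPFC", "rDLPFC"}
    sig = out[out["between_significant"]]
    outside = sig[~(sig["a"].isin(seeded) & sig["b"].isin(seeded))]
    assert len(outside) <= max(2, int(0.05 * 45))
    inside = sig[sig["a"].isin(seeded) & sig["b"].isin(seeded)]
    assert len(inside) >= 8  # ample power for dz = 0.15 at n = 30


# ---------------------------------------------------------------------------
# brain-behaviour correlation
# ---------------------------------------------------------------------------

def test_exact_linear_relation_has_unit_correlation():
    x = np.linspace(-1, 1, 20)
    res = correlate_outcome(x, 2 * x)
    assert res["r"] == pytest.approx(1.0)
    assert res["p"] == pytest.approx(0.0, abs=1e-12)


def test_independent_noise_has_null_correlation():
    rng = np.random.default_rng(7)
    res = correlate_outcome(rng.normal(0, 1, 1000), rng.normal(0, 1, 1000))
    assert abs(res["r"]) < 0.08


def test_degenerate_inputs_are_rejected():
    with pytest.raises(ValueError):
        correlate_outcome([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        correlate_outcome([1.0, 2.0], [1.0, 2.0])


def test_correlation_p_matches_t_transform():
    rng = np.random.default_rng(8)
    x = rng.normal(0, 1, 40)
    y = x + rng.normal(0, 1, 40)
    res = correlate_outcome(x, y)
    from scipy import stats

    r_ref, p_ref = stats.pearsonr(x, y)
    assert res["r"] == pytest.approx(r_ref, abs=1e-12)
    assert res["p"] == pytest.approx(p_ref, rel=1e-9)


def test_cohort_coupling_estimate_falls_in_its_sampling_interval():
    """At n = 27 the estimated PSQI-improvement vs mean-FC-change
    correlation lies inside the Fisher 95% interval around r = 0.5."""
    from nirsvft.synth import default_sim_config, simulate_cohort

    cfg = default_sim_config(seed=31, n_per_group=27, coupling_r=0.5,
                             groups=("intervention",))
    cohort = simulate_cohort(cfg)
    tr = cohort.truth.subjects
    piv = cohort.scales.pivot_table(index="subject", columns="timepoint",
                                    values="psqi_total")
    improvement = (piv["pre"] - piv["post"]).loc[sorted(tr)].to_numpy()
    delta = np.array([tr[s].delta_measured for s in sorted(tr)])
    res = correlate_outcome(delta, improvement)
    n = res["n"]
    assert abs(fisher_z(res["r"]) - fisher_z(0.5)) < 1.96 / np.sqrt(n - 3)
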