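import itertools

import numpy as np
import pandas as pd
import pytest

from cnax.segmentation import (
    CBSSegmenter,
    cbs_segment,
    impute_missing,
    max_arc_statistic,
    segment_matrix,
    smooth_outliers,
)


# ---------------------------------------------------------------------------
# outlier smoothing


def brute_force_smooth(x, k, z):
    """Literal re-implementation of the two-sided outlier rule."""
    x = np.asarray(x, float)
    obs = np.flatnonzero(~np.isnan(x))
    v = x[obs]
    med = np.median(v)
    sd = 1.4826 * np.median(np.abs(v - med))
    out = x.copy()
    flags = np.zeros(x.size, bool)
    for t in range(v.size):
        left = v[max(0, t - k):t]
        right = v[t + 1:t + k + 1]
        dl = abs(v[t] - np.median(left)) if left.size else np.inf
        dr = abs(v[t] - np.median(right)) if right.size else np.inf
        if dl > z * sd and dr > z * sd:
            nb = np.concatenate([left, right])
            m = np.median(nb)
            flags[obs[t]] = True
            out[obs[t]] = m + np.sign(v[t] - m) * z * sd
    return out, flags


def test_single_spike_flagged_and_shrunk():
    x = np.zeros(50)
    x[20] = 3.0
    out, flags = smooth_outliers(x, k=2, z=4)
    assert flags[20] and flags.sum() == 1
    assert out[20] == 0.0  # robust SD of a near-constant chromosome is 0
    assert np.all(out[np.arange(50) != 20] == 0.0)


def test_constant_sequence_has_no_flags():
    out, flags = smooth_outliers(np.full(30, 0.7), k=2, z=4)
    assert not flags.any()
    assert np.all(out == 0.7)


def test_adjacent_spikes_need_self_excluding_median():
    x = np.zeros(100)
    x[40] = x[41] = 3.0
    _, flags = smooth_outliers(x, k=2, z=4)
    assert flags[40] and flags[41]


@pytest.mark.parametrize("seed", range(5))
def test_smoothing_matches_brute_force_rule(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 0.1, 80)
    x[rng.integers(0, 80, 4)] += rng.choice([-2.5, 2.5], 4)
    x[rng.integers(0, 80, 5)] = np.nan
    out, flags = smooth_outliers(x, k=2, z=4)
    out_bf, flags_bf = brute_force_smooth(x, k=2, z=4)
    np.testing.assert_array_equal(flags, flags_bf)
    np.testing.assert_allclose(out, out_bf, equal_nan=True, atol=1e-12)


def test_short_sequence_returned_unchanged_with_warning():
    x = np.array([np.nan, 1.0, np.nan])
    with pytest.warns(UserWarning):
        out, flags = smooth_outliers(x)
    np.testing.assert_array_equal(out, x)
    assert not flags.any()


# ---------------------------------------------------------------------------
# circular arc statistic vs brute force


def brute_force_max_arc(x):
    """Enumerate every circular split once (both boundaries below n),
    pooled-variance two-sample t computed with independent arithmetic."""
    x = np.asarray(x, float)
    n = x.size
    best = None
    for i, j in itertools.combinations(range(n), 2):
        if (j - i) < 2 or (j - i) > n - 2:  # both groups need >= 2 clones
            continue
        arc = x[i:j]
        comp = np.concatenate([x[:i], x[j:]])
        ss = ((arc - arc.mean()) ** 2).sum() + ((comp - comp.mean()) ** 2).sum()
        s2 = ss / (n - 2)
        se2 = s2 * (1 / arc.size + 1 / comp.size)
        diff = abs(arc.mean() - comp.mean())
        t = (np.inf if diff > 0 else 0.0) if se2 == 0 else diff / np.sqrt(se2)
        if best is None or t > best[2]:
            best = (i, j, t)
    return best


@pytest.mark.parametrize("n", [4, 6, 8, 10, 12])
def test_arc_maximizer_matches_brute_force(n):
    rng = np.random.default_rng(100 + n)
    for _ in range(40):
        x = rng.normal(0, 1, n)
        i, j, t = max_arc_statistic(x)
        bi, bj, bt = brute_force_max_arc(x)
        assert (i, j) == (bi, bj)
        assert t == pytest.approx(bt, rel=1e-9)


# ---------------------------------------------------------------------------
# cbs_segment behavior


def test_flat_sequence_single_segment():
    segs = cbs_segment(np.full(50, 0.3), n_perm=100, seed=0)
    assert len(segs) == 1
    assert segs[0].mean == pytest.approx(0.3)
    assert (segs[0].start_index, segs[0].end_index) == (0, 50)


def test_perfect_step_split_exactly():
    x = np.concatenate([np.zeros(25), np.full(25, 0.8)])
    segs = cbs_segment(x, n_perm=200, seed=1)
    assert [(s.start_index, s.end_index) for s in segs] == [(0, 25), (25, 50)]
    assert segs[0].mean == pytest.approx(0.0, abs=1e-12)
    assert segs[1].mean == pytest.approx(0.8, abs=1e-12)


def test_short_sequence_returns_single_segment():
    segs = cbs_segment(np.array([0.1, 0.9, 0.1]), n_perm=100, seed=0)
    assert len(segs) == 1


def test_nperm_guard():
    with pytest.raises(ValueError, match="n_perm"):
        cbs_segment(np.zeros(10), n_perm=50)


def test_missing_values_reinserted_in_index_space():
    x = np.concatenate([np.zeros(20), np.full(20, 0.8)])
    x[5] = np.nan
    x[30] = np.nan
    segs = cbs_segment(x, n_perm=200, seed=2)
    assert [(s.start_index, s.end_index) for s in segs] == [(0, 20), (20, 40)]
    assert segs[0].n_probes == 19  # missing clones excluded from the mean


def test_partition_and_mean_conservation():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 0.15, 120)
    x[40:80] += 0.6
    segs = cbs_segment(x, n_perm=300, seed=4)
    # contiguous partition of the observed range
    assert segs[0].start_index == 0 and segs[-1].end_index == 120
    for a, b in zip(segs[:-1], segs[1:]):
        assert a.end_index == b.start_index
    weighted = sum(s.mean * s.n_probes for s in segs) / sum(s.n_probes for s in segs)
    assert weighted == pytest.approx(x.mean(), abs=1e-9)


def test_alpha_monotone_segment_count():
    rng = np.random.default_rng(5)
    x = rng.normal(0, 0.2, 100)
    x[30:55] += 0.45
    counts = [len(cbs_segment(x, alpha=a, n_perm=300, seed=7))
              for a in (0.001, 0.01, 0.05, 0.2)]
    assert counts == sorted(counts)


def test_fixed_seed_determinism():
    rng = np.random.default_rng(6)
    x = rng.normal(0, 0.2, 90)
    x[50:] += 0.5
    a = cbs_segment(x, n_perm=300, seed=42)
    b = cbs_segment(x, n_perm=300, seed=42)
    assert [(s.start_index, s.end_index, s.mean) for s in a] == \
           [(s.start_index, s.end_index, s.mean) for s in b]


# ---------------------------------------------------------------------------
# matrix driver + imputation


def _one_chrom_map(n):
    cm = pd.DataFrame({
        "clone_id": [f"c{i:03d}" for i in range(n)],
        "chromosome": ["chr1"] * n,
        "start": np.arange(n) * 1000,
        "end": (np.arange(n) + 1) * 1000,
        "arm": ["p"] * (n // 2) + ["q"] * (n - n // 2),
    })
    cm["position"] = (cm["start"] + cm["end"]) / 2.0
    return cm


def test_impute_missing_inside_segment_and_idempotence():
    n = 40
    cm = _one_chrom_map(n)
    x = np.concatenate([np.zeros(20), np.full(20, 0.6)])
    x[25] = np.nan
    mat = pd.DataFrame({"s1": x, "s2": x}, index=pd.Index(cm["clone_id"], name="probe_id"))
    res = segment_matrix(mat, cm, n_perm=200, seed=0, impute=True)
    assert res.smoothed.loc["c025", "s1"] == pytest.approx(0.6)
    assert res.imputed_mask.loc["c025", "s1"]
    # non-missing clones unchanged by imputation
    again = impute_missing(res, cm, original=mat)
    pd.testing.assert_frame_equal(res.smoothed, again.smoothed)


def test_all_missing_chromosome_ends_stay_missing():
    n = 30
    cm = _one_chrom_map(n)
    x = np.full(n, 0.4)
    x[:3] = np.nan  # chromosome start entirely missing
    mat = pd.DataFrame({"s1": x, "s2": x}, index=pd.Index(cm["clone_id"], name="probe_id"))
    res = segment_matrix(mat, cm, n_perm=200, seed=0, impute=True)
    assert res.smoothed.iloc[:3].isna().all().all()
    np.testing.assert_allclose(res.smoothed.iloc[3:].to_numpy(), 0.4, atol=1e-9)


def test_outlier_clone_keeps_original_value_in_smoothed():
    n = 50
    cm = _one_chrom_map(n)
    x = np.zeros(n)
    x[10] = 2.5
    mat = pd.DataFrame({"s1": x, "s2": np.zeros(n)},
                       index=pd.Index(cm["clone_id"], name="probe_id"))
    res = segment_matrix(mat, cm, n_perm=200, seed=0)
    assert res.outlier_flags.loc["c010", "s1"]
    assert res.smoothed.loc["c010", "s1"] == 2.5
    assert res.smoothed.loc["c011", "s1"] == pytest.approx(0.0)


def test_estimator_roundtrip_and_sklearn_params():
    n = 40
    cm = _one_chrom_map(n)
    rng = np.random.default_rng(8)
    X = rng.normal(0, 0.1, (3, n))
    X[:, 20:] += 0.8
    est = CBSSegmenter(clone_map=cm, n_perm=200, random_state=0)
    smoothed = est.fit_transform(X)
    assert smoothed.shape == X.shape
    assert est.segments_["sample_id"].nunique() == 3
    # the planted breakpoint and the shifted level are recovered per sample
    for _, segs in est.segments_.groupby("sample_id"):
        assert 20 in set(segs["start_index"])
    assert np.allclose(smoothed[:, 20:].mean(axis=1), 0.8, atol=0.05)
    assert est.get_params()["n_perm"] == 200
    est.set_params(alpha=0.05)
    assert est.alpha == 0.05
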