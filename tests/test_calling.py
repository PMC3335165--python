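import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cnax import calling
from cnax.calling import (
    AMP, GAIN, HOMDEL, LOSS, NEUTRAL,
    AberrationCaller, Thresholds, call_arms, call_clones,
    catalogue_events, derive_threshold, frequency, stratified_frequency,
)


def test_threshold_invariant_enforced():
    with pytest.raises(ValueError):
        Thresholds(gain=0.9, amp=0.8)


def test_derive_threshold_mean_of_profile_sds():
    rng = np.random.default_rng(0)
    profiles = np.column_stack([
        rng.normal(0, sd, 4000) for sd in (0.07, 0.075, 0.08)
    ])
    th = derive_threshold(profiles, sd_multiplier=3)
    # 3 x mean(per-profile SD) ~ 3 x 0.075 = 0.225
    assert th.gain == pytest.approx(0.225, abs=0.01)
    assert th.loss == -th.gain


def test_derive_threshold_degenerate_and_empty():
    with pytest.raises(ValueError, match="degenerate"):
        derive_threshold(np.full((100, 1), 0.1))
    with pytest.raises(ValueError, match="at least one"):
        derive_threshold(np.empty((0, 0)))


@pytest.mark.parametrize(
    "value,expected",
    [(0.30, GAIN), (0.85, AMP), (-0.75, HOMDEL), (-0.30, LOSS),
     (0.225, NEUTRAL), (-0.225, NEUTRAL), (0.8, GAIN), (-0.7, LOSS),
     (0.0, NEUTRAL), (np.nan, np.nan)],
)
def test_call_clones_thresholds_strict(value, expected):
    got = call_clones(np.array([[value]]))[0, 0]
    if np.isnan(expected):
        assert np.isnan(got)
    else:
        assert got == expected


@settings(max_examples=100, deadline=None)
@given(st.floats(-2, 2), st.floats(0, 0.5))
def test_call_monotone_in_value(value, bump):
    lo = call_clones(np.array([[value]]))[0, 0]
    hi = call_clones(np.array([[value + bump]]))[0, 0]
    assert hi >= lo


@pytest.mark.parametrize(
    "values,expected",
    [([0.3, 0.3, 0.3, 0.1], GAIN),
     ([0.3, 0.1, -0.1, -0.3], NEUTRAL),
     ([-0.3, -0.3, -0.25], LOSS)],
)
def test_call_arms_median_rule(values, expected):
    n = len(values)
    cm = pd.DataFrame({
        "clone_id": [f"c{i}" for i in range(n)], "chromosome": ["chr1"] * n,
        "start": np.arange(n), "end": np.arange(n) + 1, "arm": ["p"] * n,
    })
    mat = pd.DataFrame({"s1": values, "s2": values},
                       index=pd.Index(cm["clone_id"], name="probe_id"))
    arm = call_arms(mat, cm)
    assert arm.loc["chr1p", "s1"] == expected


def test_call_arms_all_missing_arm_is_missing(tiny_map):
    mat = pd.DataFrame(np.zeros((len(tiny_map), 2)), index=pd.Index(tiny_map["clone_id"]),
                       columns=["s1", "s2"])
    mat.iloc[:3, 0] = np.nan  # chr1 p arm of s1 entirely missing
    arm = call_arms(mat, tiny_map)
    assert np.isnan(arm.loc["chr1p", "s1"])
    assert arm.loc["chr1p", "s2"] == NEUTRAL


def _calls_df(per_sample: dict, tiny=None, chrom="chr1"):
    n = len(next(iter(per_sample.values())))
    cm = pd.DataFrame({
        "clone_id": [f"c{i}" for i in range(n)], "chromosome": [chrom] * n,
        "start": np.arange(n) * 100, "end": (np.arange(n) + 1) * 100,
        "arm": ["p"] * n,
    })
    cm["position"] = (cm["start"] + cm["end"]) / 2.0
    calls = pd.DataFrame(per_sample, index=pd.Index(cm["clone_id"], name="probe_id"),
                         dtype=float)
    return cm, calls


def test_separate_events_counted_per_run():
    cm, calls = _calls_df({"s1": [NEUTRAL, GAIN, GAIN, NEUTRAL, GAIN]})
    cat = catalogue_events(calls, cm)
    gains = cat.events[cat.events["class"] == "gain"]
    assert len(gains) == 2
    assert gains["n_probes"].tolist() == [2, 1]


def test_amp_reported_as_focal_event_and_within_gain_run():
    cm, calls = _calls_df({"s1": [GAIN, AMP, AMP, GAIN, NEUTRAL]})
    cat = catalogue_events(calls, cm)
    by_class = cat.events.groupby("class").size().to_dict()
    assert by_class == {"gain": 1, "amp": 1}
    gain_run = cat.events[cat.events["class"] == "gain"].iloc[0]
    assert (gain_run["start_index"], gain_run["end_index"]) == (0, 4)


def test_all_neutral_matrix_empty_catalogue():
    cm, calls = _calls_df({"s1": [NEUTRAL] * 5, "s2": [NEUTRAL] * 5})
    cat = catalogue_events(calls, cm)
    assert len(cat.events) == 0 and len(cat.recurrent) == 0


def test_recurrent_region_constant_carrier_sets():
    cm, calls = _calls_df({
        "s1": [GAIN, GAIN, GAIN, NEUTRAL, NEUTRAL],
        "s2": [NEUTRAL, GAIN, GAIN, GAIN, NEUTRAL],
        "s3": [NEUTRAL] * 5,
    })
    cat = catalogue_events(calls, cm)
    rec = cat.recurrent[cat.recurrent["class"] == "gain"]
    # carrier sets: {s1}, {s1,s2}, {s2} -> three maximal regions
    assert rec["n_samples"].tolist() == [1, 2, 1]
    shared = rec[rec["n_samples"] == 2].iloc[0]
    assert shared["samples"] == "s1,s2"
    assert shared["n_total"] == 3


def test_event_coverage_matches_call_counts(small_acgh):
    cm, matrix, _ = small_acgh
    calls = call_clones(matrix)
    cat = catalogue_events(calls, cm)
    arr = calls.to_numpy()
    for sample in calls.columns:
        ev = cat.events[cat.events["sample_id"] == sample]
        j = list(calls.columns).index(sample)
        col = arr[:, j]
        covered_amp = ev[ev["class"] == "amp"]["n_probes"].sum()
        assert covered_amp == int(np.nansum(col == AMP))
        covered_gain = ev[ev["class"] == "gain"]["n_probes"].sum()
        assert covered_gain == int(np.nansum(col >= GAIN))
        covered_loss = ev[ev["class"] == "loss"]["n_probes"].sum()
        assert covered_loss == int(np.nansum(col <= LOSS))


def test_frequency_fractions_and_conservation():
    cm, calls = _calls_df({f"s{i}": [GAIN if i < 4 else NEUTRAL] for i in range(10)})
    freq = frequency(calls)
    assert freq["frac_gain"].iloc[0] == pytest.approx(0.4)
    assert freq["frac_loss"].iloc[0] == 0.0
    # missing samples excluded from the denominator
    calls.iloc[0, 0] = np.nan
    freq2 = frequency(calls)
    assert freq2["n_samples"].iloc[0] == 9
    assert freq2["frac_gain"].iloc[0] == pytest.approx(3 / 9)


def test_stratified_frequency_recovers_printed_percentages():
    # group sizes 20 and 88, arm lost in 4 and 3 -> 20.0% vs 3.41%
    n1, n2 = 20, 88
    samples = [f"t{i}" for i in range(n1 + n2)]
    arm_calls = pd.DataFrame(
        {s: [LOSS if (i < 4 or n1 <= i < n1 + 3) else NEUTRAL]
         for i, s in enumerate(samples)},
        index=pd.Index(["chr19p"], name="arm"), dtype=float,
    )
    clinical = pd.DataFrame({
        "sample_id": samples,
        "stage": ["early"] * n1 + ["late"] * n2,
    })
    strat = stratified_frequency(arm_calls, clinical, "stage")
    early = strat[strat["group"] == "early"]["pct_loss"].iloc[0]
    late = strat[strat["group"] == "late"]["pct_loss"].iloc[0]
    assert early == pytest.approx(20.0)
    assert late == pytest.approx(3.41, abs=0.005)


def test_stratified_frequency_unknown_feature_and_missing_labels():
    arm_calls = pd.DataFrame({"a": [GAIN], "b": [GAIN], "c": [NEUTRAL]},
                             index=pd.Index(["chr1p"], name="arm"), dtype=float)
    clinical = pd.DataFrame({"sample_id": ["a", "b", "c"],
                             "stage": ["1", None, "1"]})
    with pytest.raises(ValueError, match="valid features"):
        stratified_frequency(arm_calls, clinical, "tumor_color")
    strat = stratified_frequency(arm_calls, clinical, "stage")
    row = strat[strat["group"] == "1"].iloc[0]
    assert row["n_samples"] == 2  # sample b excluded
    assert row["pct_gain"] == pytest.approx(50.0)


def test_caller_estimator_derives_threshold_on_fit():
    rng = np.random.default_rng(1)
    normals = rng.normal(0, 0.075, (3000, 3))
    est = AberrationCaller(normal_reference=normals)
    X = np.array([[0.3, 0.9, -0.75, 0.0]])
    est.fit(X)
    assert est.thresholds_.gain == pytest.approx(0.225, abs=0.01)
    out = est.transform(X)
    assert out.tolist() == [[GAIN, AMP, HOMDEL, NEUTRAL]]
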