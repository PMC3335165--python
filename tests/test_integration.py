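import numpy as np
import pandas as pd
import pytest

from cnax.integration import (
    DosageCorrelator,
    bh_adjust,
    binned_diagonal_analysis,
    map_expression_to_bac,
    permutation_pvalues,
    select_correlated,
)
from tests.conftest import brute_force_bh


def _maps_and_matrices(rng, n_samples=30):
    """Three BACs 0.5 Mb apart; three expression clones with known couplings."""
    cn_map = pd.DataFrame({
        "clone_id": ["b1", "b2", "b3"], "chromosome": ["chr1"] * 3,
        "start": [0, 500_000, 1_000_000], "end": [100_000, 600_000, 1_100_000],
        "arm": ["p"] * 3,
    })
    cn_map["position"] = (cn_map["start"] + cn_map["end"]) / 2.0
    expr_map = pd.DataFrame({
        "clone_id": ["e1"], "gene_symbol": ["G1"], "chromosome": ["chr1"],
        "start": [400_000], "end": [401_000], "arm": ["p"],
    })
    expr_map["position"] = (expr_map["start"] + expr_map["end"]) / 2.0
    cn = pd.DataFrame(rng.normal(0, 1, (3, n_samples)),
                      index=pd.Index(["b1", "b2", "b3"], name="probe_id"),
                      columns=[f"s{i}" for i in range(n_samples)])
    return cn_map, expr_map, cn


def test_best_correlated_bac_selected():
    rng = np.random.default_rng(0)
    cn_map, expr_map, cn = _maps_and_matrices(rng)
    expr = pd.DataFrame([cn.loc["b2"] + rng.normal(0, 0.3, cn.shape[1])],
                        index=pd.Index(["e1"], name="probe_id"), columns=cn.columns)
    recs = map_expression_to_bac(expr, expr_map, cn, cn_map)
    assert recs.loc[0, "mapped_bac_id"] == "b2"
    assert recs.loc[0, "r"] > 0.8


def test_window_excludes_distant_bacs():
    rng = np.random.default_rng(1)
    cn_map, expr_map, cn = _maps_and_matrices(rng)
    two = pd.DataFrame({
        "clone_id": ["e1", "e2"], "gene_symbol": ["G1", "G2"],
        "chromosome": ["chr1"] * 2, "start": [400_000, 2_400_000],
        "end": [401_000, 2_401_000], "arm": ["p"] * 2,
    })
    two["position"] = (two["start"] + two["end"]) / 2.0
    expr = pd.DataFrame(rng.normal(0, 1, (2, cn.shape[1])),
                        index=pd.Index(["e1", "e2"], name="probe_id"), columns=cn.columns)
    recs = map_expression_to_bac(expr, two, cn, cn_map).set_index("expr_clone_id")
    assert recs.loc["e1", "mapped"]
    assert not recs.loc["e2", "mapped"]  # 1.35 Mb from the nearest BAC midpoint


def test_tied_correlation_resolved_by_distance():
    # identical copy-number profiles at two distances -> nearer BAC wins
    n = 30
    rng = np.random.default_rng(2)
    base = rng.normal(0, 1, n)
    cn_map = pd.DataFrame({
        "clone_id": ["near", "far2"], "chromosome": ["chr1"] * 2,
        "start": [300_000, 900_000], "end": [300_100, 900_100], "arm": ["p"] * 2,
    })
    cn_map["position"] = (cn_map["start"] + cn_map["end"]) / 2.0
    expr_map = pd.DataFrame({"clone_id": ["e1"], "gene_symbol": ["G1"],
                             "chromosome": ["chr1"], "start": [200_000],
                             "end": [201_000], "arm": ["p"]})
    expr_map["position"] = (expr_map["start"] + expr_map["end"]) / 2.0
    cols = [f"s{i}" for i in range(n)]
    cn = pd.DataFrame([base, base], index=pd.Index(["near", "far2"], name="probe_id"),
                      columns=cols)
    expr = pd.DataFrame([base + rng.normal(0, 0.1, n)],
                        index=pd.Index(["e1"], name="probe_id"), columns=cols)
    recs = map_expression_to_bac(expr, expr_map, cn, cn_map)
    assert recs.loc[0, "mapped_bac_id"] == "near"


def test_assembly_mismatch_raises():
    rng = np.random.default_rng(3)
    cn_map, expr_map, cn = _maps_and_matrices(rng)
    other = expr_map.assign(chromosome=["chr9"])
    expr = pd.DataFrame(rng.normal(0, 1, (1, cn.shape[1])),
                        index=pd.Index(["e1"], name="probe_id"), columns=cn.columns)
    with pytest.raises(ValueError, match="assembly"):
        map_expression_to_bac(expr, other, cn, cn_map)


def test_permutation_pvalue_definition_and_determinism():
    rng = np.random.default_rng(4)
    cn_map, expr_map, cn = _maps_and_matrices(rng, n_samples=40)
    expr = pd.DataFrame([cn.loc["b2"] * 0.9 + rng.normal(0, 0.2, cn.shape[1])],
                        index=pd.Index(["e1"], name="probe_id"), columns=cn.columns)
    recs = map_expression_to_bac(expr, expr_map, cn, cn_map)
    out1 = permutation_pvalues(recs, expr, cn, n_perm=200, seed=9)
    out2 = permutation_pvalues(recs, expr, cn, n_perm=200, seed=9)
    assert out1["p_perm"].equals(out2["p_perm"])
    # a strong true correlation beats essentially every shuffle
    assert out1.loc[0, "p_perm"] <= 0.01
    # plain proportion vs pseudo-count estimator
    out3 = permutation_pvalues(recs, expr, cn, n_perm=200, seed=9, pseudo_count=True)
    assert out3.loc[0, "p_perm"] == pytest.approx(
        (out1.loc[0, "p_perm"] * 200 + 1) / 201)


def test_reselecting_null_is_at_least_as_conservative():
    """Re-choosing the best 1-Mb partner under each shuffle maximizes the
    permuted r, so the resulting p can only grow."""
    rng = np.random.default_rng(21)
    cn_map, expr_map, cn = _maps_and_matrices(rng, n_samples=40)
    expr = pd.DataFrame([cn.loc["b2"] * 0.5 + rng.normal(0, 0.6, cn.shape[1])],
                        index=pd.Index(["e1"], name="probe_id"), columns=cn.columns)
    recs = map_expression_to_bac(expr, expr_map, cn, cn_map)
    plain = permutation_pvalues(recs, expr, cn, n_perm=300, seed=3)
    resel = permutation_pvalues(recs, expr, cn, n_perm=300, seed=3,
                                reselect=True, expr_map=expr_map, cn_map=cn_map)
    assert resel.loc[0, "p_perm"] >= plain.loc[0, "p_perm"]
    with pytest.raises(ValueError, match="expr_map"):
        permutation_pvalues(recs, expr, cn, n_perm=300, seed=3, reselect=True)


def test_selection_exchangeability_keeps_almost_nothing_under_the_null():
    """With expression decoupled from copy number, the r/q selection keeps
    at most ~2% of clones."""
    from cnax.validation import _independent_pair

    expr, expr_map, cn, cn_map = _independent_pair(13, n_clones=400, n_samples=40)
    recs = map_expression_to_bac(expr, expr_map, cn, cn_map)
    recs = permutation_pvalues(recs, expr, cn, n_perm=200, seed=13)
    recs["q"] = bh_adjust(recs["p_perm"].to_numpy())
    subset, _ = select_correlated(recs)
    assert len(subset) / len(recs) <= 0.02


def test_constant_expression_clone_dropped():
    rng = np.random.default_rng(5)
    cn_map, expr_map, cn = _maps_and_matrices(rng)
    expr = pd.DataFrame(np.full((1, cn.shape[1]), 0.7),
                        index=pd.Index(["e1"], name="probe_id"), columns=cn.columns)
    recs = map_expression_to_bac(expr, expr_map, cn, cn_map)
    assert not recs.loc[0, "mapped"]  # zero-variance r undefined


def test_bh_adjust_worked_example_and_edges():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
    np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
    q = bh_adjust([0.01, np.nan, 0.04])
    assert np.isnan(q[1])
    np.testing.assert_allclose(q[[0, 2]], brute_force_bh([0.01, 0.04]))


def test_bh_adjust_matches_brute_force_on_random_vectors():
    rng = np.random.default_rng(6)
    for _ in range(1000):
        p = rng.random(rng.integers(1, 40))
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)


def test_select_correlated_cutoffs_and_achieved_fdr():
    records = pd.DataFrame({
        "expr_clone_id": ["a", "b", "c"],
        "r": [0.30, 0.28, 0.50],
        "p_perm": [0.001, 0.0005, 0.002],
        "q": [0.005, 0.001, 0.008],
        "mapped": [True] * 3,
    })
    subset, fdr = select_correlated(records)
    assert subset["expr_clone_id"].tolist() == ["a", "c"]  # b fails r > 0.29
    assert fdr == pytest.approx(0.008)
    empty, fdr0 = select_correlated(records.iloc[:0])
    assert len(empty) == 0 and np.isnan(fdr0)


def _binned_setup(coupled: bool, seed: int, n_samples=40):
    from cnax.simulate import (AberrationEvent, SimulationConfig, make_clone_map,
                               make_expression_map, simulate_acgh, simulate_expression)

    cfg = SimulationConfig(
        n_samples=n_samples, n_chromosomes=4, clones_per_chrom=40,
        n_expr_clones=300, missing_rate=0.0, seed=seed,
        dosage_gene_fraction=0.6 if coupled else 0.0,
        dosage_effect=1.0 if coupled else 0.0,
        aberration_spec=(
            AberrationEvent("chr1", 0, 20, 0.6, 0.5),
            AberrationEvent("chr2", 20, 40, -0.6, 0.5),
            AberrationEvent("chr3", 10, 30, 0.6, 0.5),
        ),
    )
    cm = make_clone_map(cfg)
    acgh, truth = simulate_acgh(cm, cfg)
    em = make_expression_map(cfg)
    expr, truth = simulate_expression(em, cm, truth, cfg)
    return expr, em, truth.true_segment_means + 0.0, cm


def test_binned_diagonal_contrast_coupled_vs_decoupled():
    expr, em, cn, cm = _binned_setup(coupled=True, seed=7)
    res = binned_diagonal_analysis(expr, em, cn, cm)
    assert res.median_diagonal - res.median_offdiagonal >= 0.05
    expr0, em0, cn0, cm0 = _binned_setup(coupled=False, seed=8)
    res0 = binned_diagonal_analysis(expr0, em0, cn0, cm0)
    assert abs(res0.median_diagonal - res0.median_offdiagonal) < 0.05


def test_single_short_arm_forms_one_bin():
    cm = pd.DataFrame({
        "clone_id": ["b1", "b2"], "chromosome": ["chr1"] * 2,
        "start": [0, 1_000_000], "end": [100_000, 1_100_000], "arm": ["p"] * 2,
    })
    cm["position"] = (cm["start"] + cm["end"]) / 2.0
    rng = np.random.default_rng(9)
    cols = [f"s{i}" for i in range(12)]
    cn = pd.DataFrame(rng.normal(size=(2, 12)), index=pd.Index(cm["clone_id"]), columns=cols)
    res = binned_diagonal_analysis(cn, cm, cn, cm, bin_bp=20_000_000)
    assert res.matrix.shape == (1, 1)


def test_dosage_correlator_estimator_end_to_end():
    rng = np.random.default_rng(10)
    cn_map, expr_map, cn = _maps_and_matrices(rng, n_samples=40)
    expr = pd.DataFrame([cn.loc["b2"] + rng.normal(0, 0.3, cn.shape[1])],
                        index=pd.Index(["e1"], name="probe_id"), columns=cn.columns)
    est = DosageCorrelator(expr_map=expr_map, cn_map=cn_map, n_perm=200, random_state=0)
    est.fit(expr.T, cn.T)
    assert est.n_selected_ == 1
    assert est.records_.loc[0, "q"] <= 0.01
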