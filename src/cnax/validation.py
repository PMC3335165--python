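"""Parameter-recovery and calibration experiments on synthetic data.

These experiments quantify how well each stage recovers planted truth under
the generator's study conditions: threshold derivation from normal-vs-normal
noise, CBS breakpoint recovery and false-split rate, permutation-null
calibration, FDR control and power of the correlation selection, and the
diagonal contrast of the binned correlation map.  Both the test suite and
the reproduction script call into this module so the reported numbers are
always recomputed from scratch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import integration
from .calling import Thresholds, call_clones, derive_threshold
from .segmentation import cbs_segment, segment_matrix
from .simulate import (
    AberrationEvent,
    SimulationConfig,
    dosage_effect_for_target_r,
    make_clone_map,
    make_expression_map,
    simulate_acgh,
    simulate_expression,
)


def threshold_recovery(seed: int, n_clones: int = 2300, n_profiles: int = 3,
                       noise_sd: float = 0.075, sd_multiplier: float = 3.0) -> dict:
    """Derive the gain threshold from simulated normal-vs-normal profiles."""
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 101]))
    profiles = rng.normal(0.0, noise_sd, size=(n_clones, n_profiles))
    th = derive_threshold(profiles, sd_multiplier=sd_multiplier)
    return {"gain_threshold": th.gain, "n": n_clones * n_profiles}


def cbs_breakpoint_recovery(
    seed: int, n_sims: int = 50, n_clones: int = 200,
    breakpoints: tuple[int, ...] = (60, 140), shift: float = 0.5,
    noise_sd: float = 0.15, alpha: float = 0.01, n_perm: int = 1000,
    tol: int = 2, n_null: int = 200,
) -> dict:
    """Breakpoint recovery on planted steps plus false-split rate on flat nulls.

    Each simulated chromosome is 0 outside the middle stretch and ``shift``
    inside it, so both planted breakpoints carry |shift| in log2 units.
    A breakpoint counts as recovered when a fitted boundary lies within
    ``tol`` clones of it.
    """
    found = 0
    total = 0
    for s in range(n_sims):
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 201, s]))
        x = rng.normal(0.0, noise_sd, n_clones)
        x[breakpoints[0]:breakpoints[1]] += shift
        segs = cbs_segment(x, alpha=alpha, n_perm=n_perm, seed=seed * 1000 + s)
        bounds = {b for seg in segs for b in (seg.start_index, seg.end_index)}
        for bp in breakpoints:
            total += 1
            if any(abs(b - bp) <= tol for b in bounds):
                found += 1
    false_splits = 0
    for s in range(n_null):
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 202, s]))
        x = rng.normal(0.0, noise_sd, n_clones)
        segs = cbs_segment(x, alpha=alpha, n_perm=n_perm, seed=seed * 2000 + s)
        if len(segs) > 1:
            false_splits += 1
    return {
        "recovery_fraction": found / total,
        "false_split_rate": false_splits / n_null,
        "n_sims": n_sims,
        "n_null": n_null,
    }


def _independent_pair(seed: int, n_clones: int, n_samples: int):
    """Expression/copy-number matrices with no coupling, plus aligned maps."""
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 301]))
    spacing = 1_500_000
    cn_map = pd.DataFrame({
        "clone_id": [f"b{i:04d}" for i in range(n_clones)],
        "chromosome": ["chr1"] * n_clones,
        "start": np.arange(n_clones, dtype=np.int64) * spacing,
        "end": (np.arange(n_clones, dtype=np.int64) + 1) * spacing,
        "arm": ["p"] * n_clones,
    })
    cn_map["position"] = (cn_map["start"] + cn_map["end"]) / 2.0
    expr_map = cn_map.copy()
    expr_map["clone_id"] = [f"e{i:04d}" for i in range(n_clones)]
    expr_map["gene_symbol"] = [f"G{i:04d}" for i in range(n_clones)]
    cols = [f"s{i}" for i in range(n_samples)]
    cn = pd.DataFrame(rng.normal(0, 1, (n_clones, n_samples)),
                      index=pd.Index(cn_map["clone_id"], name="probe_id"), columns=cols)
    expr = pd.DataFrame(rng.normal(0, 1, (n_clones, n_samples)),
                        index=pd.Index(expr_map["clone_id"], name="probe_id"), columns=cols)
    return expr, expr_map, cn, cn_map


def null_calibration(seed: int, n_clones: int = 500, n_samples: int = 62,
                     n_perm: int = 1000) -> dict:
    """Uniformity of permutation p-values under fully independent data."""
    expr, expr_map, cn, cn_map = _independent_pair(seed, n_clones, n_samples)
    records = integration.map_expression_to_bac(expr, expr_map, cn, cn_map)
    records = integration.permutation_pvalues(records, expr, cn,
                                              n_perm=n_perm, seed=seed)
    p = records["p_perm"].dropna().to_numpy()
    ks = stats.ks_1samp(p, stats.uniform.cdf).statistic
    return {
        "fraction_p_below_0.05": float(np.mean(p < 0.05)),
        "ks_distance": float(ks),
        "n": int(p.size),
    }


def _mixture_config(seed: int, n_samples: int = 62, target_r: float = 0.6) -> SimulationConfig:
    """Every chromosome fully aberrant in half the samples, 10% dosage genes.

    The dosage slope is set so the population correlation between a dosage
    gene's expression and the (nearly noiseless) smoothed copy number is the
    requested target.
    """
    shift, frac, expr_sd = 0.6, 0.5, 0.3
    beta = dosage_effect_for_target_r(target_r, shift, frac, expr_sd)
    events = tuple(
        AberrationEvent(f"chr{c + 1}", 0, 50, shift if c % 2 == 0 else -shift, frac)
        for c in range(4)
    )
    return SimulationConfig(
        n_samples=n_samples, n_chromosomes=4, clones_per_chrom=50,
        aberration_spec=events, n_expr_clones=500,
        dosage_gene_fraction=0.1, dosage_effect=beta, expr_noise_sd=expr_sd,
        independent_de_fraction=0.0, seed=seed,
    )


def fdr_and_power(seed: int, n_reps: int = 20, cbs_n_perm: int = 500,
                  corr_n_perm: int = 1000, r_cut: float = 0.29,
                  q_cut: float = 0.01) -> dict:
    """Empirical FDR and sensitivity of the r/q selection on mixture data."""
    fdrs, sens = [], []
    for rep in range(n_reps):
        cfg = _mixture_config(seed=(seed * 7919 + rep) & 0x7FFFFFFF)
        cm = make_clone_map(cfg)
        acgh, truth = simulate_acgh(cm, cfg)
        res = segment_matrix(acgh, cm, n_perm=cbs_n_perm, seed=cfg.seed)
        em = make_expression_map(cfg)
        expr, truth = simulate_expression(em, cm, truth, cfg)
        records = integration.map_expression_to_bac(expr, em, res.smoothed, cm)
        records = integration.permutation_pvalues(records, expr, res.smoothed,
                                                  n_perm=corr_n_perm, seed=cfg.seed)
        records["q"] = integration.bh_adjust(records["p_perm"].to_numpy())
        selected, _ = integration.select_correlated(records, r_cut=r_cut, q_cut=q_cut)
        truth_set = truth.dosage_gene_ids
        n_sel = len(selected)
        tp = int(selected["expr_clone_id"].isin(truth_set).sum())
        fdrs.append((n_sel - tp) / n_sel if n_sel else 0.0)
        sens.append(tp / len(truth_set))
    return {
        "empirical_fdr": float(np.mean(fdrs)),
        "sensitivity": float(np.mean(sens)),
        "n_reps": n_reps,
    }


def full_synthetic_run(seed: int, config: SimulationConfig | None = None,
                       cbs_n_perm: int = 1000, corr_n_perm: int = 1000,
                       r_cut: float = 0.29, q_cut: float = 0.01,
                       min_imbalance: int = 5) -> dict:
    """Simulate -> segment -> call -> integrate -> nominate, in memory.

    Returns every intermediate plus the nomination result, for end-to-end
    checks that need to cross-examine stages against the planted truth.
    """
    from . import candidates as cand_mod
    from .simulate import de_list_from_truth

    import dataclasses

    cfg = config or SimulationConfig(seed=seed)
    if cfg.seed != seed:
        cfg = dataclasses.replace(cfg, seed=seed)
    cm = make_clone_map(cfg)
    acgh, truth = simulate_acgh(cm, cfg)
    em = make_expression_map(cfg)
    expr, truth = simulate_expression(em, cm, truth, cfg)
    de = de_list_from_truth(em, truth)
    seg = segment_matrix(acgh, cm, n_perm=cbs_n_perm, seed=cfg.seed)
    calls = call_clones(acgh)
    records = integration.map_expression_to_bac(expr, em, seg.smoothed, cm)
    records = integration.permutation_pvalues(records, expr, seg.smoothed,
                                              n_perm=corr_n_perm, seed=cfg.seed)
    records["q"] = integration.bh_adjust(records["p_perm"].to_numpy())
    selected, achieved = integration.select_correlated(records, r_cut=r_cut, q_cut=q_cut)
    nomination = cand_mod.nominate(selected, calls, de, min_imbalance=min_imbalance)
    return {
        "config": cfg, "clone_map": cm, "acgh": acgh, "expr_map": em,
        "expr": expr, "de": de, "truth": truth, "segmentation": seg,
        "calls": calls, "records": records, "selected": selected,
        "achieved_fdr": achieved, "nomination": nomination,
    }


def _diagonal_config(seed: int, coupled: bool) -> SimulationConfig:
    """Genome-wide copy-number variability, as in real tumor panels.

    Every chromosome carries an arm-scale aberration in half the samples
    (tumor genomes vary everywhere, not only at a few recurrent loci), and
    a quarter of expression clones are dosage-responsive, mirroring the
    genome-wide fraction of copy-number-correlated transcripts such panels
    show.  The decoupled variant zeroes the dosage slope only.
    """
    events = tuple(
        AberrationEvent(f"chr{c + 1}", 0, 40, 0.6 if c % 2 == 0 else -0.6, 0.5)
        for c in range(4)
    )
    return SimulationConfig(
        n_samples=40, n_chromosomes=4, clones_per_chrom=40,
        aberration_spec=events, n_expr_clones=400,
        dosage_gene_fraction=0.25 if coupled else 0.0,
        dosage_effect=1.0 if coupled else 0.0,
        independent_de_fraction=0.0, seed=seed,
    )


def diagonal_contrast(seed: int, coupled: bool, n_reps: int = 20,
                      cbs_n_perm: int = 200, bin_bp: float = 20_000_000) -> dict:
    """Median diagonal vs off-diagonal binned correlation, averaged over reps."""
    diags, offs = [], []
    for rep in range(n_reps):
        cfg = _diagonal_config((seed * 6151 + rep + (0 if coupled else 5000)) & 0x7FFFFFFF,
                               coupled)
        cm = make_clone_map(cfg)
        acgh, truth = simulate_acgh(cm, cfg)
        res = segment_matrix(acgh, cm, n_perm=cbs_n_perm, seed=cfg.seed)
        em = make_expression_map(cfg)
        expr, truth = simulate_expression(em, cm, truth, cfg)
        b = integration.binned_diagonal_analysis(expr, em, res.smoothed, cm, bin_bp=bin_bp)
        diags.append(b.median_diagonal)
        offs.append(b.median_offdiagonal)
    return {
        "median_diagonal": float(np.mean(diags)),
        "median_offdiagonal": float(np.mean(offs)),
        "difference": float(np.mean(diags) - np.mean(offs)),
        "n_reps": n_reps,
    }
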