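"""Copy-number / expression dosage correlation with a permutation null.

Each cDNA expression clone is mapped to the BAC copy-number clone within
1 Mb of it (midpoint to midpoint) that maximizes the Pearson correlation
between the clone's expression and the CBS-smoothed copy-number values over
the shared samples.  Significance is calibrated by label-shuffle
permutation: the expression sample labels are globally shuffled (one shuffle
per replicate shared by all clones, preserving between-clone dependence),
the per-clone correlations recomputed against the already-chosen BAC, and
the one-sided p-value is the proportion of replicates with permuted r >=
observed r.  Benjamini-Hochberg adjustment then controls the FDR, and
clones with r > 0.29 and q < 0.01 are selected as dosage-responsive.

A 20-Mb binned map of average pairwise correlations between expression bins
and copy-number bins summarizes the genome-wide cis effect: coupled data
show elevated correlation on the diagonal (a bin with itself) relative to
off-diagonal bin pairs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

RECORD_COLUMNS = [
    "expr_clone_id", "gene_symbol", "mapped_bac_id", "distance_bp",
    "r", "n_used", "p_perm", "q",
]


def _pairwise_corr(a: np.ndarray, b: np.ndarray, min_n: int = 10):
    """Pearson r of two 1-D arrays over pairwise-complete entries."""
    m = ~np.isnan(a) & ~np.isnan(b)
    n = int(m.sum())
    if n < min_n:
        return np.nan, n
    x, y = a[m], b[m]
    xc = x - x.mean()
    yc = y - y.mean()
    vx = (xc * xc).sum()
    vy = (yc * yc).sum()
    if vx <= 1e-18 or vy <= 1e-18:  # constant vectors: r undefined
        return np.nan, n
    den = np.sqrt(vx * vy)
    return float((xc * yc).sum() / den), n


def map_expression_to_bac(
    expr: pd.DataFrame, expr_map: pd.DataFrame,
    smoothed_cn: pd.DataFrame, cn_map: pd.DataFrame,
    window_bp: float = 1_000_000, min_n: int = 10,
) -> pd.DataFrame:
    """Assign each expression clone its best-correlated BAC within 1 Mb.

    Ties in r are broken by smaller midpoint distance, then lexicographic
    BAC id.  Clones with no candidate BAC (or no candidate yielding a valid
    correlation) are returned with ``mapped`` False and excluded downstream.
    """
    shared = expr.columns.intersection(smoothed_cn.columns)
    if len(shared) < min_n:
        raise ValueError(f"only {len(shared)} shared samples; need >= {min_n}")
    e_vals = expr.loc[:, shared]
    c_vals = smoothed_cn.loc[:, shared]
    cn_pos = cn_map["position"].to_numpy()
    cn_chrom = cn_map["chromosome"].to_numpy()
    cn_ids = cn_map["clone_id"].to_numpy()
    cn_row = {cid: k for k, cid in enumerate(smoothed_cn.index)}

    rows = []
    any_candidates = False
    e_chrom_arr = expr_map["chromosome"].to_numpy()
    e_pos_arr = expr_map["position"].to_numpy()
    e_ids = expr_map["clone_id"].to_numpy()
    genes = expr_map["gene_symbol"].to_numpy() if "gene_symbol" in expr_map else np.array([""] * len(expr_map))
    c_arr = c_vals.to_numpy(dtype=float)
    e_arr = e_vals.reindex(pd.Index(e_ids)).to_numpy(dtype=float)

    for chrom in pd.unique(e_chrom_arr):
        block = np.flatnonzero(cn_chrom == chrom)
        bpos = cn_pos[block]
        for gi in np.flatnonzero(e_chrom_arr == chrom):
            epos = e_pos_arr[gi]
            lo = np.searchsorted(bpos, epos - window_bp, side="left")
            hi = np.searchsorted(bpos, epos + window_bp, side="right")
            cand = block[lo:hi]
            best = None
            for ck in cand:
                cid = cn_ids[ck]
                if cid not in cn_row:
                    continue
                any_candidates = True
                r, n = _pairwise_corr(e_arr[gi], c_arr[cn_row[cid]], min_n=min_n)
                if np.isnan(r):
                    continue
                key = (-r, abs(cn_pos[ck] - epos), str(cid))
                if best is None or key < best[0]:
                    best = (key, cid, abs(cn_pos[ck] - epos), r, n)
            if best is None:
                rows.append((e_ids[gi], genes[gi], None, np.nan, np.nan, 0, False))
            else:
                rows.append((e_ids[gi], genes[gi], best[1], best[2], best[3], best[4], True))
    if not any_candidates and len(rows):
        raise ValueError(
            "no expression clone has any BAC candidate within the window; "
            "likely a genome-assembly mismatch between the two clone maps"
        )
    records = pd.DataFrame(
        rows,
        columns=["expr_clone_id", "gene_symbol", "mapped_bac_id", "distance_bp",
                 "r", "n_used", "mapped"],
    )
    logger.info("mapped %d / %d expression clones", int(records["mapped"].sum()), len(records))
    return records


def _rowwise_corr_matrix(A: np.ndarray, B: np.ndarray, min_n: int = 10) -> np.ndarray:
    """Row-by-row Pearson r of two equal-shape matrices, pairwise complete."""
    M = ~np.isnan(A) & ~np.isnan(B)
    n = M.sum(axis=1)
    A0 = np.where(M, A, 0.0)
    B0 = np.where(M, B, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sa = A0.sum(1); sb = B0.sum(1)
        saa = (A0 * A0).sum(1); sbb = (B0 * B0).sum(1); sab = (A0 * B0).sum(1)
        nf = np.maximum(n, 1).astype(float)
        cov = sab - sa * sb / nf
        va = saa - sa * sa / nf
        vb = sbb - sb * sb / nf
        r = cov / np.sqrt(va * vb)
    r[(n < min_n) | (va <= 0) | (vb <= 0)] = np.nan
    return r


def permutation_pvalues(
    records: pd.DataFrame, expr: pd.DataFrame, smoothed_cn: pd.DataFrame,
    n_perm: int = 1000, seed: int = 0, min_n: int = 10,
    pseudo_count: bool = False, scan_negative: bool = False,
    reselect: bool = False, expr_map: pd.DataFrame | None = None,
    cn_map: pd.DataFrame | None = None, window_bp: float = 1_000_000,
) -> pd.DataFrame:
    """One-sided permutation p-values for the mapped correlation records.

    All records share the same global label shuffle within each replicate.
    ``pseudo_count`` switches the plain k/B proportion to (k+1)/(B+1).
    ``scan_negative`` tests |r| instead of r (off by default: the selection
    targets positive dosage correlations).  ``reselect`` re-runs the
    best-partner choice under every shuffle (the permuted statistic becomes
    the max r over the clone's 1-Mb candidate set, a more conservative
    null); it requires ``expr_map`` and ``cn_map``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    recs = records.copy()
    mapped = recs["mapped"].fillna(False).astype(bool) & recs["r"].notna()
    shared = expr.columns.intersection(smoothed_cn.columns)
    E = expr.loc[:, shared].reindex(recs.loc[mapped, "expr_clone_id"]).to_numpy(dtype=float)
    if reselect:
        if expr_map is None or cn_map is None:
            raise ValueError("reselect=True requires expr_map and cn_map")
        pair_rec, C = _candidate_pairs(
            recs.loc[mapped, "expr_clone_id"], expr_map,
            smoothed_cn.loc[:, shared], cn_map, window_bp,
        )
        E = E[pair_rec]  # one row per (record, candidate) pair
        n_records = int(mapped.sum())
    else:
        C = smoothed_cn.loc[:, shared].reindex(recs.loc[mapped, "mapped_bac_id"]).to_numpy(dtype=float)
        pair_rec = None
        n_records = E.shape[0]
    r_obs = recs.loc[mapped, "r"].to_numpy(dtype=float)
    if scan_negative:
        r_obs = np.abs(r_obs)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 17]))
    n_s = len(shared)
    exceed = np.zeros(n_records, dtype=np.int64)
    valid = np.zeros(n_records, dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(n_s)
        r_p = _rowwise_corr_matrix(E[:, perm], C, min_n=min_n)
        if scan_negative:
            r_p = np.abs(r_p)
        if pair_rec is not None:
            r_p = _groupwise_max(r_p, pair_rec, n_records)
        ok = ~np.isnan(r_p)
        valid += ok
        exceed += np.where(ok & (r_p >= r_obs), 1, 0)
    denom = np.maximum(valid, 1).astype(float)
    if pseudo_count:
        p = (exceed + 1) / (denom + 1)
    else:
        p = exceed / denom
    p = np.where(valid == 0, np.nan, p)
    recs["p_perm"] = np.nan
    recs.loc[mapped, "p_perm"] = p
    dropped = int(mapped.sum() - np.isfinite(p).sum())
    if dropped:
        warnings.warn(f"{dropped} records dropped: too few complete samples under permutation",
                      stacklevel=2)
    return recs


def _candidate_pairs(expr_clone_ids, expr_map, cn_values, cn_map, window_bp):
    """(record index, BAC row) pairs for every 1-Mb candidate of each record."""
    epos = expr_map.set_index("clone_id")["position"]
    echrom = expr_map.set_index("clone_id")["chromosome"]
    cn_pos = cn_map["position"].to_numpy()
    cn_chrom = cn_map["chromosome"].to_numpy()
    cn_ids = cn_map["clone_id"].to_numpy()
    row_of = {cid: k for k, cid in enumerate(cn_values.index)}
    rec_idx, rows = [], []
    for k, eid in enumerate(expr_clone_ids):
        block = np.flatnonzero(cn_chrom == echrom[eid])
        near = block[np.abs(cn_pos[block] - epos[eid]) <= window_bp]
        for ck in near:
            if cn_ids[ck] in row_of:
                rec_idx.append(k)
                rows.append(row_of[cn_ids[ck]])
    C = cn_values.to_numpy(dtype=float)[rows]
    return np.asarray(rec_idx, dtype=np.int64), C


def _groupwise_max(values: np.ndarray, groups: np.ndarray, n_groups: int) -> np.ndarray:
    """Per-group max treating NaN as missing; all-NaN groups stay NaN."""
    out = np.full(n_groups, -np.inf)
    ok = ~np.isnan(values)
    np.maximum.at(out, groups[ok], values[ok])
    out[out == -np.inf] = np.nan
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaN propagates."""
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        if (p[ok] < 0).any() or (p[ok] > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def select_correlated(records: pd.DataFrame, r_cut: float = 0.29, q_cut: float = 0.01):
    """Keep records with r > r_cut and q < q_cut; report the achieved FDR bound.

    Returns ``(subset, achieved_fdr)`` where the achieved FDR is the largest
    BH q among the kept records (NaN when nothing is kept).
    """
    recs = records
    if "q" not in recs.columns or recs["q"].isna().all():
        recs = recs.copy()
        recs["q"] = bh_adjust(recs["p_perm"].to_numpy())
    keep = (recs["r"] > r_cut) & (recs["q"] < q_cut)
    keep = keep.fillna(False)
    subset = recs.loc[keep].copy()
    achieved = float(subset["q"].max()) if len(subset) else float("nan")
    return subset, achieved


# ---------------------------------------------------------------------------
# binned diagonal analysis


@dataclass
class BinnedCorrelationMap:
    """Average pairwise correlation between 20-Mb expression and CN bins."""

    matrix: pd.DataFrame       # expression bins x copy-number bins
    bins: pd.DataFrame         # bin metadata shared by both axes
    diagonal_mask: pd.DataFrame
    median_diagonal: float
    median_offdiagonal: float
    bin_bp: float


def _bin_labels(cmap: pd.DataFrame, bin_bp: float) -> pd.Series:
    """(chromosome, arm, bin ordinal) per probe, bins anchored at the arm start."""
    labels = []
    key = list(zip(cmap["chromosome"], cmap["arm"]))
    arm_start: dict = {}
    for k, (chrom, arm) in enumerate(key):
        arm_start.setdefault((chrom, arm), cmap["start"].iat[k])
        arm_start[(chrom, arm)] = min(arm_start[(chrom, arm)], cmap["start"].iat[k])
    for k, (chrom, arm) in enumerate(key):
        b = int((cmap["position"].iat[k] - arm_start[(chrom, arm)]) // bin_bp)
        labels.append(f"{chrom}{arm}:{b}")
    return pd.Series(labels, index=cmap["clone_id"].to_numpy())


def _standardize_rows(values: pd.DataFrame) -> np.ndarray:
    """Row-standardize with per-row mean imputation of missing entries."""
    arr = values.to_numpy(dtype=float)
    mu = np.nanmean(arr, axis=1, keepdims=True)
    arr = np.where(np.isnan(arr), mu, arr)
    arr = arr - arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = arr / sd
    z[~np.isfinite(z)] = np.nan
    return z


def binned_diagonal_analysis(
    expr: pd.DataFrame, expr_map: pd.DataFrame,
    smoothed_cn: pd.DataFrame, cn_map: pd.DataFrame,
    bin_bp: float = 20_000_000,
) -> BinnedCorrelationMap:
    """Average pairwise Pearson correlation for every (expr bin, CN bin) pair.

    Each chromosome arm is divided into bins of ``bin_bp``; an arm shorter
    than one bin forms a single bin.  Bin pairs with no probes on either
    side are missing and excluded from the diagonal/off-diagonal medians.
    Missing sample values are mean-imputed per probe before standardizing.
    """
    shared = expr.columns.intersection(smoothed_cn.columns)
    e_bins = _bin_labels(expr_map, bin_bp)
    c_bins = _bin_labels(cn_map, bin_bp)
    Ze = _standardize_rows(expr.loc[:, shared].reindex(e_bins.index))
    Zc = _standardize_rows(smoothed_cn.loc[:, shared].reindex(c_bins.index))
    ok_e = ~np.isnan(Ze).any(axis=1)
    ok_c = ~np.isnan(Zc).any(axis=1)
    Ze, e_lab = Ze[ok_e], e_bins.to_numpy()[ok_e]
    Zc, c_lab = Zc[ok_c], c_bins.to_numpy()[ok_c]
    n = len(shared)
    R = (Ze @ Zc.T) / n  # rows standardized with population sd -> divide by n

    all_bins = sorted(set(e_lab) | set(c_lab), key=_bin_sort_key)
    bin_ix = {b: k for k, b in enumerate(all_bins)}
    Ie = np.zeros((len(all_bins), Ze.shape[0]))
    Ic = np.zeros((len(all_bins), Zc.shape[0]))
    for k, b in enumerate(e_lab):
        Ie[bin_ix[b], k] = 1.0
    for k, b in enumerate(c_lab):
        Ic[bin_ix[b], k] = 1.0
    counts = np.outer(Ie.sum(1), Ic.sum(1))
    sums = Ie @ R @ Ic.T
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = sums / counts
    avg[counts == 0] = np.nan
    matrix = pd.DataFrame(avg, index=all_bins, columns=all_bins)
    diag = pd.DataFrame(np.eye(len(all_bins), dtype=bool), index=all_bins, columns=all_bins)
    vals = matrix.to_numpy()
    dmask = diag.to_numpy()
    present = ~np.isnan(vals)
    med_diag = float(np.median(vals[dmask & present])) if (dmask & present).any() else float("nan")
    med_off = float(np.median(vals[~dmask & present])) if (~dmask & present).any() else float("nan")
    bins = pd.DataFrame({"bin": all_bins})
    return BinnedCorrelationMap(
        matrix=matrix, bins=bins, diagonal_mask=diag,
        median_diagonal=med_diag, median_offdiagonal=med_off, bin_bp=bin_bp,
    )


def _bin_sort_key(label: str):
    from .io import chromosome_sort_key

    body, b = label.rsplit(":", 1)
    chrom, arm = body[:-1], body[-1]
    return (chromosome_sort_key(chrom), arm, int(b))


# ---------------------------------------------------------------------------
# estimator facade


class DosageCorrelator(BaseEstimator):
    """Expression-to-copy-number dosage correlation as a fit-shaped estimator.

    ``fit(X, Y)`` takes expression ``X`` of shape (n_samples, n_expr_probes)
    and smoothed copy number ``Y`` of shape (n_samples, n_bac_probes), in the
    order of ``expr_map`` / ``cn_map``.  After fitting:

    Attributes
    ----------
    records_ : DataFrame of per-clone mapping, r, permutation p and BH q.
    selected_ : records passing ``r > r_cut`` and ``q < q_cut``.
    achieved_fdr_ : max q among selected records.
    """

    def __init__(self, expr_map=None, cn_map=None, window_bp: float = 1_000_000,
                 n_perm: int = 1000, r_cut: float = 0.29, q_cut: float = 0.01,
                 min_n: int = 10, pseudo_count: bool = False,
                 scan_negative: bool = False, reselect: bool = False,
                 random_state: int = 0):
        self.expr_map = expr_map
        self.cn_map = cn_map
        self.window_bp = window_bp
        self.n_perm = n_perm
        self.r_cut = r_cut
        self.q_cut = q_cut
        self.min_n = min_n
        self.pseudo_count = pseudo_count
        self.scan_negative = scan_negative
        self.reselect = reselect
        self.random_state = random_state

    def fit(self, X, Y):
        if self.expr_map is None or self.cn_map is None:
            raise ValueError("expr_map and cn_map are required")
        expr = self._frame(X, self.expr_map)
        cn = self._frame(Y, self.cn_map)
        records = map_expression_to_bac(
            expr, self.expr_map, cn, self.cn_map,
            window_bp=self.window_bp, min_n=self.min_n,
        )
        records = permutation_pvalues(
            records, expr, cn, n_perm=self.n_perm, seed=self.random_state,
            min_n=self.min_n, pseudo_count=self.pseudo_count,
            scan_negative=self.scan_negative, reselect=self.reselect,
            expr_map=self.expr_map, cn_map=self.cn_map, window_bp=self.window_bp,
        )
        records["q"] = bh_adjust(records["p_perm"].to_numpy())
        self.records_ = records
        self.selected_, self.achieved_fdr_ = select_correlated(
            records, r_cut=self.r_cut, q_cut=self.q_cut
        )
        self.n_selected_ = len(self.selected_)
        return self

    @staticmethod
    def _frame(X, cmap) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X.T if list(X.columns) == list(cmap["clone_id"]) else X
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != len(cmap):
            raise ValueError("X must be (n_samples, n_probes) matching the map")
        return pd.DataFrame(arr.T, index=pd.Index(cmap["clone_id"], name="probe_id"),
                            columns=[f"s{i}" for i in range(arr.shape[0])])
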