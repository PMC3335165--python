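"""Circular binary segmentation of per-sample log2-ratio profiles.

The segmenter translates a noisy ordered sequence of per-clone copy-number
log2 ratios into piecewise-constant regions of equal copy number.  The
recursive step treats the current stretch of clones as a circle, scans every
arc (i, j] for the largest absolute Welch t-statistic between the clones on
the arc and those off it, and judges the best arc against a permutation
reference distribution: the sequence is shuffled ``n_perm`` times and the
p-value is the plain proportion of shuffles whose maximal arc statistic
reaches the observed one.  Significant arcs contribute their boundaries as
change points and the pieces are segmented recursively; adjacent segments
whose means differ by less than ``merge_tol`` are merged afterwards.

Before segmentation, isolated outlier clones (deviating from the median of
their +/-k index neighbours by more than z robust SDs of the chromosome) are
shrunk towards that neighbour median for change-point testing only; reported
"smoothed" values keep the originally observed ratio at outlier clones.
Missing clones are removed from the index arithmetic and re-inserted
afterwards; those falling inside a segment's genomic span are imputed with
the segment mean.

Permutations for each candidate split are seeded from the global seed plus
the segment's coordinates, so a segment's p-value does not depend on the
recursion path that reached it.  Permutation generation stops early once the
exceedance count already guarantees p > alpha; the accept/reject decision is
always identical to the full-``n_perm`` decision.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# outlier smoothing


def smooth_outliers(values, k: int = 2, z: float = 4.0):
    """Flag and shrink isolated outlier clones in one chromosome's sequence.

    A non-missing clone is an outlier when it deviates from the medians of
    BOTH its left-side and right-side windows of up to ``k`` non-missing
    neighbours (self excluded) by more than ``z`` times the chromosome's
    robust SD (1.4826 x median absolute deviation).  Requiring both sides
    keeps the first clone of a genuine copy-number step from being flagged
    (it agrees with its own segment's side) while isolated spikes, which
    disagree with both sides, are caught.  A side with no neighbours (the
    chromosome ends) is ignored.  Outliers are shrunk to the +/-k
    neighbour median +/- z x robust SD for change-point testing; the caller
    keeps the original values for reporting.

    Returns ``(shrunk_values, outlier_flags)`` aligned with the input;
    missing values pass through untouched.
    """
    x = np.asarray(values, dtype=float).copy()
    flags = np.zeros(x.shape, dtype=bool)
    obs = np.flatnonzero(~np.isnan(x))
    if obs.size < 3:
        warnings.warn("fewer than 3 non-missing values; outlier smoothing skipped", stacklevel=2)
        return x, flags
    v = x[obs]
    med = np.median(v)
    robust_sd = 1.4826 * np.median(np.abs(v - med))
    n = v.size
    pad = np.full(k, np.nan)
    vp = np.concatenate([pad, v, pad])
    left = np.empty((k, n))
    right = np.empty((k, n))
    for d in range(1, k + 1):
        left[d - 1] = vp[k - d: k - d + n]
        right[d - 1] = vp[k + d: k + d + n]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        left_med = np.nanmedian(left, axis=0)
        right_med = np.nanmedian(right, axis=0)
        both_med = np.nanmedian(np.concatenate([left, right], axis=0), axis=0)
    thr = z * robust_sd
    dev_left = np.abs(v - left_med)
    dev_right = np.abs(v - right_med)
    dev_left[np.isnan(left_med)] = np.inf   # no neighbours on that side
    dev_right[np.isnan(right_med)] = np.inf
    out = (dev_left > thr) & (dev_right > thr)
    shrunk = v.copy()
    shrunk[out] = both_med[out] + np.sign(v[out] - both_med[out]) * thr
    x[obs] = shrunk
    flags[obs] = out
    return x, flags


# ---------------------------------------------------------------------------
# circular arc statistic


@lru_cache(maxsize=64)
def _arc_pairs(n: int):
    """Canonical circular split boundaries 0 <= i < j <= n-1.

    On a circle of n points a split is an unordered boundary pair; taking
    both boundaries below n enumerates each split exactly once (the arc
    (j, n] is the complement of (0, j] and would duplicate it).  Both the
    arc and its complement must hold at least 2 clones: a singleton group
    has an ill-defined variance and, worse, the maximal singleton statistic
    is invariant under permutation, which would blind the reference
    distribution (isolated single-clone excursions are the outlier
    smoother's job).  Enumeration order (i ascending, then j ascending)
    realizes the declared tie-break: smaller start index first, then
    shorter arc.
    """
    i, j = np.triu_indices(n, k=2)
    keep = (j - i) <= n - 2
    return i[keep], j[keep]


@lru_cache(maxsize=64)
def _arc_constants(n: int):
    """Arc boundary pairs plus the pooled-t size factor 1/n_a + 1/n_c."""
    i, j = _arc_pairs(n)
    na = (j - i).astype(float)
    c1 = 1.0 / na + 1.0 / (n - na)
    return i, j, c1


def _max_arc_stat(X: np.ndarray):
    """Maximal pooled-variance |t| over all arcs, per row of ``X`` ((B, n)).

    The statistic for arc x[i:j] against its complement is the classical
    two-sample t with the variance pooled over both groups,
    ``|m_a - m_c| / sqrt(s2 (1/n_a + 1/n_c))`` with
    ``s2 = (SS_a + SS_c) / (n - 2)``.  Pooling keeps short arcs comparable
    to long ones (a per-group variance would explode for two coincidentally
    close neighbours).  Zero pooled variance: the statistic is +inf when
    the means differ, else 0.  Returns (i, j, t) arrays of length B.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    B, n = X.shape
    i, j, c1 = _arc_constants(n)
    Xc = X - X.mean(axis=1, keepdims=True)
    S = np.concatenate([np.zeros((B, 1)), np.cumsum(Xc, axis=1)], axis=1)
    qt = np.einsum("bi,bi->b", Xc, Xc)  # total centered sum of squares
    # After centering, t^2 = (n-2) g / (qt - g) with g = c1 * (arc sum)^2,
    # a strictly increasing function of g: maximize g over the grid and
    # recover t for the winning arc only.
    g = S[:, j] - S[:, i]
    np.multiply(g, g, out=g)
    np.multiply(g, c1, out=g)
    k = np.argmax(g, axis=1)  # first occurrence == declared tie-break
    rows = np.arange(B)
    gmax = g[rows, k]
    resid = np.maximum(qt - gmax, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = (n - 2) * gmax / resid
    t2[resid == 0] = np.where(gmax[resid == 0] > 0, np.inf, 0.0)
    return i[k], j[k], np.sqrt(t2)


def max_arc_statistic(x: np.ndarray):
    """Best circular arc of a single sequence: ``(i, j, |t|)``."""
    i, j, t = _max_arc_stat(np.asarray(x, dtype=float)[None, :])
    return int(i[0]), int(j[0]), float(t[0])


def _split_pvalue(x: np.ndarray, t_obs: float, alpha: float, n_perm: int,
                  rng: np.random.Generator):
    """Permutation decision for one candidate split, with certified early stop.

    Returns (significant, p_estimate, n_done).  When stopping early because
    the exceedance count already exceeds alpha * n_perm, the reject decision
    equals the full-n_perm decision; the returned p is then a lower-bounded
    estimate from the permutations actually drawn.
    """
    reject_count = alpha * n_perm  # exceedances beyond this force p > alpha
    exceed = 0
    done = 0
    batch = 64
    while done < n_perm:
        b = min(batch, n_perm - done)
        P = rng.permuted(np.tile(x, (b, 1)), axis=1)
        _, _, tmax = _max_arc_stat(P)
        exceed += int(np.sum(tmax >= t_obs))
        done += b
        if exceed > reject_count:
            return False, exceed / done, done
        batch = min(batch * 2, 256)
    p = exceed / n_perm
    return p <= alpha, p, n_perm


# ---------------------------------------------------------------------------
# recursive segmentation


@dataclass
class Segment:
    """A maximal run of clones sharing one fitted copy-number level."""

    sample_id: str | None
    chromosome: str | None
    start_index: int  # inclusive, in the chromosome's clone index space
    end_index: int    # exclusive
    mean: float
    n_probes: int


def _segment_observed(v: np.ndarray, alpha: float, n_perm: int,
                      entropy: tuple) -> list[int]:
    """Breakpoints (observed-index space) of a compacted sequence.

    ``entropy`` is a tuple of integers identifying (seed, sample, chromosome);
    each tested stretch derives its permutation stream from it plus the
    stretch's own coordinates.
    """
    n = v.size
    boundaries = {0, n}

    def recurse(lo: int, hi: int) -> None:
        m = hi - lo
        if m < 4:
            return
        seg = v[lo:hi]
        i, j, t_obs = _max_arc_stat(seg[None, :])
        i, j, t_obs = int(i[0]), int(j[0]), float(t_obs[0])
        if t_obs == 0.0:
            return
        rng = np.random.default_rng(np.random.SeedSequence(list(entropy) + [lo, hi]))
        significant, _, _ = _split_pvalue(seg, t_obs, alpha, n_perm, rng)
        if not significant:
            return
        cuts = sorted({i, j} - {0, m})
        if not cuts:
            return
        for a, b in zip([0] + cuts, cuts + [m]):
            recurse(lo + a, lo + b)
        boundaries.update(lo + c for c in cuts)

    recurse(0, n)
    return sorted(boundaries)


def _merge_boundaries(v: np.ndarray, bps: list[int], merge_tol: float) -> list[int]:
    """Drop interior boundaries between segments whose means are within tol."""
    bps = list(bps)
    changed = True
    while changed and len(bps) > 2:
        changed = False
        means = [v[a:b].mean() for a, b in zip(bps[:-1], bps[1:])]
        diffs = [abs(m2 - m1) for m1, m2 in zip(means[:-1], means[1:])]
        if diffs:
            k = int(np.argmin(diffs))
            if diffs[k] < merge_tol:
                del bps[k + 1]
                changed = True
    return bps


def cbs_segment(values, alpha: float = 0.01, n_perm: int = 1000, seed=0,
                merge_tol: float = 0.05, sample_id=None, chromosome=None,
                _entropy=None) -> list[Segment]:
    """Segment one chromosome's ordered log2 ratios.

    ``values`` may contain NaN; missing clones are excluded from index
    arithmetic and segments are reported in the original index space, each
    spanning from its first to its last observed clone.  Sequences shorter
    than 4 observed clones yield a single segment.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a stable permutation p-value")
    x = np.asarray(values, dtype=float)
    obs = np.flatnonzero(~np.isnan(x))
    if obs.size == 0:
        return []
    v = x[obs]
    entropy = _entropy if _entropy is not None else (int(seed) & 0x7FFFFFFF,)
    if v.size < 4:
        bps = [0, v.size]
    else:
        bps = _segment_observed(v, alpha, n_perm, tuple(entropy))
        bps = _merge_boundaries(v, bps, merge_tol)
    segments = []
    for a, b in zip(bps[:-1], bps[1:]):
        segments.append(
            Segment(
                sample_id=sample_id,
                chromosome=chromosome,
                start_index=int(obs[a]),
                end_index=int(obs[b - 1]) + 1,
                mean=float(v[a:b].mean()),
                n_probes=int(b - a),
            )
        )
    return segments


# ---------------------------------------------------------------------------
# matrix-level driver


@dataclass
class SegmentationResult:
    """Segments plus the per-clone 'smoothed' matrix used downstream.

    ``smoothed`` holds the segment mean for ordinary clones, the originally
    observed ratio for flagged outlier clones, and (after imputation) the
    segment mean for missing clones inside a segment's span.  Clones outside
    any segment remain missing and are listed in ``unimputed``.
    """

    segments: pd.DataFrame
    smoothed: pd.DataFrame
    outlier_flags: pd.DataFrame
    imputed_mask: pd.DataFrame | None = None
    params: dict = field(default_factory=dict)


def segment_matrix(
    matrix: pd.DataFrame,
    clone_map: pd.DataFrame,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
    merge_tol: float = 0.05,
    outlier_k: int = 2,
    outlier_z: float = 4.0,
    impute: bool = True,
) -> SegmentationResult:
    """CBS over every sample x chromosome of a probes-x-samples matrix."""
    cm = clone_map.reset_index(drop=True)
    matrix = matrix.reindex(pd.Index(cm["clone_id"], name=matrix.index.name))
    chroms = cm["chromosome"].to_numpy()
    chrom_list = list(pd.unique(chroms))
    arr = matrix.to_numpy(dtype=float)
    smoothed = np.full(arr.shape, np.nan)
    flags = np.zeros(arr.shape, dtype=bool)
    seg_rows = []
    base_seed = int(seed) & 0x7FFFFFFF
    for j, sample in enumerate(matrix.columns):
        for ci, chrom in enumerate(chrom_list):
            block = np.flatnonzero(chroms == chrom)
            raw = arr[block, j]
            if np.isnan(raw).all():
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                shrunk, fl = smooth_outliers(raw, k=outlier_k, z=outlier_z)
            flags[block, j] = fl
            segs = cbs_segment(
                shrunk, alpha=alpha, n_perm=n_perm, merge_tol=merge_tol,
                sample_id=sample, chromosome=chrom,
                _entropy=(base_seed, j, ci),
            )
            for s in segs:
                gi, gj = block[s.start_index], block[s.end_index - 1] + 1
                seg_rows.append(
                    (sample, chrom, int(cm["start"].iat[gi]), int(cm["end"].iat[gj - 1]),
                     int(gi), int(gj), s.n_probes, s.mean)
                )
                members = block[s.start_index:s.end_index]
                present = ~np.isnan(raw[s.start_index:s.end_index])
                smoothed[members[present], j] = s.mean
            # outlier clones keep their originally observed ratio
            out_idx = block[fl]
            smoothed[out_idx, j] = arr[out_idx, j]
    segments = pd.DataFrame(
        seg_rows,
        columns=["sample_id", "chromosome", "start_bp", "end_bp",
                 "start_index", "end_index", "n_probes", "mean"],
    )
    result = SegmentationResult(
        segments=segments,
        smoothed=pd.DataFrame(smoothed, index=matrix.index, columns=matrix.columns),
        outlier_flags=pd.DataFrame(flags, index=matrix.index, columns=matrix.columns),
        params={"alpha": alpha, "n_perm": n_perm, "seed": seed, "merge_tol": merge_tol,
                "outlier_k": outlier_k, "outlier_z": outlier_z},
    )
    if impute:
        result = impute_missing(result, cm, original=matrix)
    return result


def impute_missing(result: SegmentationResult, clone_map: pd.DataFrame,
                   original: pd.DataFrame | None = None) -> SegmentationResult:
    """Fill missing clones lying inside a segment's genomic span with its mean.

    Clones outside every segment (e.g. all-missing chromosome ends) remain
    missing; non-missing clones are never altered (idempotent).
    """
    cm = clone_map.reset_index(drop=True)
    smoothed = result.smoothed.to_numpy(dtype=float).copy()
    imputed = np.zeros(smoothed.shape, dtype=bool)
    pos = cm["position"].to_numpy() if "position" in cm else (cm["start"].to_numpy() + cm["end"].to_numpy()) / 2.0
    chroms = cm["chromosome"].to_numpy()
    col_of = {s: k for k, s in enumerate(result.smoothed.columns)}
    orig_arr = original.to_numpy(dtype=float) if original is not None else None
    for seg in result.segments.itertuples(index=False):
        j = col_of[seg.sample_id]
        inside = (
            (chroms == seg.chromosome)
            & (pos >= seg.start_bp)
            & (pos < seg.end_bp)
        )
        fill = inside & np.isnan(smoothed[:, j])
        if orig_arr is not None:
            fill &= np.isnan(orig_arr[:, j])
        smoothed[fill, j] = seg.mean
        imputed[fill, j] = True
    logger.debug("imputation filled %d values", int(imputed.sum()))
    return SegmentationResult(
        segments=result.segments,
        smoothed=pd.DataFrame(smoothed, index=result.smoothed.index, columns=result.smoothed.columns),
        outlier_flags=result.outlier_flags,
        imputed_mask=pd.DataFrame(imputed, index=result.smoothed.index, columns=result.smoothed.columns),
        params=result.params,
    )


class CBSSegmenter(TransformerMixin, BaseEstimator):
    """Circular-binary-segmentation smoother with a sklearn transformer surface.

    ``fit(X)``/``transform(X)`` take ``X`` of shape (n_samples, n_probes) in
    clone-map order; each biological sample is segmented independently, so
    nothing is carried from fit data to transform data beyond parameters.
    ``fit`` stores the segmentation of the fitted matrix in ``segments_``
    and the smoothed matrix in ``smoothed_``.

    Parameters mirror :func:`segment_matrix`.  ``clone_map`` may be omitted,
    in which case all probes form one synthetic chromosome.
    """

    def __init__(self, clone_map: pd.DataFrame | None = None, alpha: float = 0.01,
                 n_perm: int = 1000, merge_tol: float = 0.05, outlier_k: int = 2,
                 outlier_z: float = 4.0, impute: bool = True, random_state: int = 0):
        self.clone_map = clone_map
        self.alpha = alpha
        self.n_perm = n_perm
        self.merge_tol = merge_tol
        self.outlier_k = outlier_k
        self.outlier_z = outlier_z
        self.impute = impute
        self.random_state = random_state

    def _as_matrix(self, X) -> tuple[pd.DataFrame, pd.DataFrame]:
        if isinstance(X, pd.DataFrame):
            samples = X.index.astype(str)
            arr = X.to_numpy(dtype=float)
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim != 2:
                raise ValueError("X must be 2-D (n_samples, n_probes)")
            samples = pd.Index([f"s{i}" for i in range(arr.shape[0])])
        cm = self.clone_map
        if cm is None:
            n = arr.shape[1]
            cm = pd.DataFrame(
                {
                    "clone_id": [f"probe_{i:05d}" for i in range(n)],
                    "chromosome": ["chr1"] * n,
                    "start": np.arange(n, dtype=np.int64) * 1_000_000,
                    "end": (np.arange(n, dtype=np.int64) + 1) * 1_000_000,
                    "arm": ["p"] * n,
                }
            )
            cm["position"] = (cm["start"] + cm["end"]) / 2.0
        if arr.shape[1] != len(cm):
            raise ValueError(
                f"X has {arr.shape[1]} probes but the clone map has {len(cm)}"
            )
        matrix = pd.DataFrame(arr.T, index=pd.Index(cm["clone_id"], name="probe_id"),
                              columns=samples)
        return matrix, cm

    def fit(self, X, y=None):
        matrix, cm = self._as_matrix(X)
        self.result_ = segment_matrix(
            matrix, cm, alpha=self.alpha, n_perm=self.n_perm,
            seed=self.random_state, merge_tol=self.merge_tol,
            outlier_k=self.outlier_k, outlier_z=self.outlier_z, impute=self.impute,
        )
        self.segments_ = self.result_.segments
        self.smoothed_ = self.result_.smoothed.to_numpy(dtype=float).T
        self.outlier_flags_ = self.result_.outlier_flags.to_numpy().T
        self.n_features_in_ = matrix.shape[0]
        return self

    def transform(self, X):
        """Segment ``X`` and return the smoothed (n_samples, n_probes) matrix."""
        matrix, cm = self._as_matrix(X)
        res = segment_matrix(
            matrix, cm, alpha=self.alpha, n_perm=self.n_perm,
            seed=self.random_state, merge_tol=self.merge_tol,
            outlier_k=self.outlier_k, outlier_z=self.outlier_z, impute=self.impute,
        )
        return res.smoothed.to_numpy(dtype=float).T

    def fit_transform(self, X, y=None):
        self.fit(X)
        return self.smoothed_
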