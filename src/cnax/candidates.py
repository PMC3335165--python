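"""Candidate oncogene / tumor-suppressor nomination and clustering.

A dosage-responsive expression clone (from the correlation selection)
becomes a candidate oncogene when its mapped BAC shows at least 5 more
gain-or-amp calls than loss-or-homdel calls across samples and the clone is
up-regulated in tumors, and a candidate tumor suppressor in the mirrored
case.  Records whose copy-number imbalance direction contradicts their
differential-expression direction are excluded and logged.  Gene-level
roll-up keeps one representative clone per gene (largest r); genes whose
clones disagree on the class are reported as conflicts, never collapsed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator

from .calling import GAIN, LOSS

logger = logging.getLogger(__name__)


def gain_loss_imbalance(records: pd.DataFrame, calls: pd.DataFrame) -> pd.DataFrame:
    """Attach n_gain / n_loss / imbalance counted at each record's mapped BAC.

    Gains count calls in {gain, amp}, losses {loss, homdel}; missing calls
    are excluded from both counts.
    """
    out = records.copy()
    arr = calls.to_numpy(dtype=float)
    row_of = {cid: k for k, cid in enumerate(calls.index)}
    n_gain, n_loss = [], []
    for bac in out["mapped_bac_id"]:
        if bac is None or (isinstance(bac, float) and np.isnan(bac)):
            n_gain.append(np.nan)
            n_loss.append(np.nan)
            continue
        if bac not in row_of:
            raise KeyError(f"mapped BAC {bac!r} absent from the call matrix")
        col = arr[row_of[bac]]
        n_gain.append(int(np.nansum(np.nan_to_num(col, nan=0.0) >= GAIN)))
        n_loss.append(int(np.nansum((np.nan_to_num(col, nan=0.0) <= LOSS) & ~np.isnan(col))))
    out["n_gain"] = n_gain
    out["n_loss"] = n_loss
    out["imbalance"] = out["n_gain"] - out["n_loss"]
    return out


@dataclass
class NominationResult:
    candidates: pd.DataFrame
    discordant: pd.DataFrame
    gene_rollup: pd.DataFrame
    gene_conflicts: pd.DataFrame = field(default_factory=pd.DataFrame)


def nominate(
    records_selected: pd.DataFrame, calls: pd.DataFrame, de: pd.DataFrame,
    min_imbalance: int = 5,
) -> NominationResult:
    """Apply the three-criterion filter to the selected correlation records.

    Criteria: (1) membership in ``records_selected`` (r and q cutoffs
    already applied); (2) |gains - losses| >= ``min_imbalance`` at the
    mapped BAC; (3) presence in the differential-expression list with a
    direction concordant with the imbalance (gain & up -> oncogene,
    loss & down -> tsg).  Discordant clones are returned separately.
    """
    if "direction" not in de.columns:
        raise ValueError("DE list must carry a 'direction' column (up/down)")
    recs = gain_loss_imbalance(records_selected, calls)
    de_dir = de.set_index("expr_clone_id")["direction"]
    recs = recs[recs["expr_clone_id"].isin(de_dir.index)].copy()
    recs["de_direction"] = de_dir.reindex(recs["expr_clone_id"]).to_numpy()
    passing = recs[recs["imbalance"].abs() >= min_imbalance].copy()
    concordant = (
        ((passing["imbalance"] >= min_imbalance) & (passing["de_direction"] == "up"))
        | ((passing["imbalance"] <= -min_imbalance) & (passing["de_direction"] == "down"))
    )
    candidates = passing[concordant].copy()
    discordant = passing[~concordant].copy()
    if len(discordant):
        logger.info("%d clones excluded as discordant (imbalance vs DE direction)", len(discordant))
    candidates["class"] = np.where(candidates["imbalance"] > 0, "oncogene", "tsg")

    rollup_rows, conflict_rows = [], []
    for gene, grp in candidates.groupby("gene_symbol", sort=True):
        classes = set(grp["class"])
        rep = grp.loc[grp["r"].idxmax()]
        if len(classes) > 1:
            conflict_rows.append((gene, len(grp), ",".join(sorted(classes))))
            continue
        rollup_rows.append((gene, rep["expr_clone_id"], rep["class"], float(rep["r"]),
                            int(rep["imbalance"]), len(grp)))
    gene_rollup = pd.DataFrame(
        rollup_rows,
        columns=["gene_symbol", "representative_clone", "class", "r", "imbalance", "n_clones"],
    )
    gene_conflicts = pd.DataFrame(conflict_rows, columns=["gene_symbol", "n_clones", "classes"])
    return NominationResult(
        candidates=candidates.reset_index(drop=True),
        discordant=discordant.reset_index(drop=True),
        gene_rollup=gene_rollup,
        gene_conflicts=gene_conflicts,
    )


# ---------------------------------------------------------------------------
# hierarchical clustering of candidate expression patterns


@dataclass
class ClusteringResult:
    """Average-linkage clustering under 1 - centered Pearson distance."""

    sample_linkage: np.ndarray | None
    clone_linkage: np.ndarray | None
    sample_order: list
    clone_order: list
    ordered: pd.DataFrame


def _correlation_linkage(X: np.ndarray, method: str = "average", metric: str = "correlation"):
    if X.shape[0] < 2:
        return None, [0] if X.shape[0] else []
    if X.shape[1] < 2 and metric == "correlation":
        # centered Pearson is undefined on length-1 vectors
        warnings.warn("falling back to euclidean distance for length-1 profiles", stacklevel=2)
        metric = "euclidean"
    d = pdist(X, metric=metric)
    d = np.clip(np.nan_to_num(d, nan=2.0), 0.0, None)
    Z = hierarchy.linkage(d, method=method)
    order = hierarchy.leaves_list(Z).tolist()
    return Z, order


def cluster_candidates(
    expr_values: pd.DataFrame, method: str = "average", metric: str = "correlation",
) -> ClusteringResult:
    """Cluster samples and candidate clones by their expression patterns.

    ``expr_values`` is clones x samples.  Constant rows are dropped with a
    warning (their centered-correlation distance is undefined).  Missing
    values are mean-imputed per clone for distance computation only.
    """
    if expr_values.shape[1] < 2:
        raise ValueError("at least 2 samples required for clustering")
    arr = expr_values.to_numpy(dtype=float)
    mu = np.nanmean(arr, axis=1, keepdims=True)
    arr = np.where(np.isnan(arr), mu, arr)
    sd = arr.std(axis=1)
    keep = sd > 0
    if (~keep).any():
        warnings.warn(f"dropping {int((~keep).sum())} constant candidate rows", stacklevel=2)
    arr = arr[keep]
    clones = expr_values.index[keep]
    if arr.shape[0] == 0:
        raise ValueError("no non-constant candidate rows to cluster")
    clone_Z, clone_order = _correlation_linkage(arr, method, metric)
    sample_Z, sample_order = _correlation_linkage(arr.T, method, metric)
    ordered = pd.DataFrame(arr, index=clones, columns=expr_values.columns)
    ordered = ordered.iloc[clone_order, :].iloc[:, sample_order]
    return ClusteringResult(
        sample_linkage=sample_Z,
        clone_linkage=clone_Z,
        sample_order=[expr_values.columns[i] for i in sample_order],
        clone_order=[clones[i] for i in clone_order],
        ordered=ordered,
    )


def export_cdt(result: ClusteringResult, path) -> None:
    """Write the ordered matrix as a CDT-like tab-delimited heatmap export."""
    out = result.ordered.copy()
    out.index.name = "CLONE"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")


class CandidateNominator(BaseEstimator):
    """Three-criterion candidate filter with a fit-shaped surface.

    ``fit(records_selected)`` with the call matrix and DE list supplied at
    construction; results land in ``candidates_``, ``discordant_``,
    ``gene_rollup_`` and ``gene_conflicts_``.
    """

    def __init__(self, calls: pd.DataFrame | None = None, de: pd.DataFrame | None = None,
                 min_imbalance: int = 5):
        self.calls = calls
        self.de = de
        self.min_imbalance = min_imbalance

    def fit(self, X, y=None):
        if self.calls is None or self.de is None:
            raise ValueError("calls and de are required")
        res = nominate(X, self.calls, self.de, min_imbalance=self.min_imbalance)
        self.candidates_ = res.candidates
        self.discordant_ = res.discordant
        self.gene_rollup_ = res.gene_rollup
        self.gene_conflicts_ = res.gene_conflicts
        return self
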