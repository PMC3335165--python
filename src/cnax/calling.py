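"""Copy-number aberration calling from log2-ratio profiles.

Per-clone calls are ordinal: homozygous deletion < loss < neutral < gain <
amplification, encoded as integers -2..2.  The clone-level gain/loss
threshold is three times the average per-profile SD of normal-vs-normal
hybridizations (0.225 log2 units for the arrays this package models); the
amplification and homozygous-deletion cutoffs are fixed at 0.8 and -0.7.
All comparisons are strict, so a value exactly at a threshold stays in the
lower (more neutral) class.  Arm-level calls use the median log2 ratio of
all clones on the arm against the same +/-0.225 cutoffs.

Calls operate on raw per-clone ratios by default; CBS-smoothed values are
reserved for the expression-correlation analysis (a ``smoothed`` call mode
exists for sensitivity checks via the caller estimator's input, since
calling is a pure function of whatever matrix is supplied).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

HOMDEL, LOSS, NEUTRAL, GAIN, AMP = -2, -1, 0, 1, 2
CALL_LABELS = {HOMDEL: "homdel", LOSS: "loss", NEUTRAL: "neutral", GAIN: "gain", AMP: "amp"}
LABEL_CODES = {v: k for k, v in CALL_LABELS.items()}


@dataclass(frozen=True)
class Thresholds:
    """Log2-ratio cutoffs for the five ordinal aberration classes."""

    gain: float = 0.225
    loss: float = -0.225
    amp: float = 0.8
    homdel: float = -0.7
    sd_multiplier: float = 3.0

    def __post_init__(self) -> None:
        if not (self.homdel < self.loss < 0 < self.gain < self.amp):
            raise ValueError(
                f"thresholds must satisfy homdel < loss < 0 < gain < amp, got {self}"
            )


def derive_threshold(
    normal_normal,
    sd_multiplier: float = 3.0,
    amp: float = 0.8,
    homdel: float = -0.7,
) -> Thresholds:
    """Derive the gain/loss cutoff from normal-vs-normal hybridizations.

    The cutoff is ``sd_multiplier`` times the average of the per-profile
    standard deviations of the reference log2 ratios; loss is its negative.
    The focal amplification / homozygous-deletion cutoffs are configured
    independently.
    """
    values = np.asarray(normal_normal, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    if values.size == 0 or values.shape[1] == 0:
        raise ValueError("at least one normal-vs-normal profile is required")
    with np.errstate(invalid="ignore"):
        sds = np.array([np.nanstd(values[:, j], ddof=1) for j in range(values.shape[1])])
    if np.isnan(sds).any() or (sds < 1e-12).any():
        raise ValueError("degenerate reference: a normal profile has zero variance")
    gain = float(sd_multiplier * sds.mean())
    return Thresholds(gain=gain, loss=-gain, amp=amp, homdel=homdel, sd_multiplier=sd_multiplier)


def _call_array(values: np.ndarray, th: Thresholds) -> np.ndarray:
    calls = np.full(values.shape, np.nan)
    with np.errstate(invalid="ignore"):
        calls = np.where(values > th.amp, AMP,
                 np.where(values > th.gain, GAIN,
                  np.where(values < th.homdel, HOMDEL,
                   np.where(values < th.loss, LOSS, NEUTRAL)))).astype(float)
    calls[np.isnan(values)] = np.nan
    return calls


def call_clones(values: pd.DataFrame, thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Per-clone ordinal calls; missing input stays missing."""
    th = thresholds or Thresholds()
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(
            _call_array(values.to_numpy(dtype=float), th),
            index=values.index, columns=values.columns,
        )
    return _call_array(np.asarray(values, dtype=float), th)


def call_arms(
    values: pd.DataFrame, clone_map: pd.DataFrame, thresholds: Thresholds | None = None
) -> pd.DataFrame:
    """Arm-level gain/loss/neutral calls from median log2 ratios.

    Arms with zero non-missing clones in a sample yield a missing call.
    """
    th = thresholds or Thresholds()
    arm_key = clone_map["chromosome"].astype(str) + clone_map["arm"].astype(str)
    medians = values.groupby(arm_key.to_numpy()).median()
    # preserve genome order of arms
    order = arm_key[~arm_key.duplicated()].tolist()
    medians = medians.reindex(order)
    m = medians.to_numpy(dtype=float)
    calls = np.where(m > th.gain, GAIN, np.where(m < th.loss, LOSS, NEUTRAL)).astype(float)
    calls[np.isnan(m)] = np.nan
    out = pd.DataFrame(calls, index=medians.index, columns=medians.columns)
    out.index.name = "arm"
    return out


@dataclass
class EventCatalogue:
    """Per-sample aberration events and cross-sample recurrent regions.

    Gain events are maximal runs of gain-or-amp clones (amplifications also
    appear as their own focal events, nested in the enclosing gain run);
    losses symmetrically enclose homozygous deletions.  Each run is a
    separate event, so several gains on one chromosome count separately.
    """

    events: pd.DataFrame = field(default_factory=pd.DataFrame)
    recurrent: pd.DataFrame = field(default_factory=pd.DataFrame)


_CLASS_MASKS = {
    "gain": lambda c: c >= GAIN,
    "loss": lambda c: c <= LOSS,
    "amp": lambda c: c == AMP,
    "homdel": lambda c: c == HOMDEL,
}


def _runs(mask: np.ndarray):
    """Maximal runs of True, as (start, end) half-open index pairs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    return list(zip(starts.tolist(), ends.tolist()))


def catalogue_events(calls: pd.DataFrame, clone_map: pd.DataFrame) -> EventCatalogue:
    """Enumerate per-sample events and maximal constant-carrier recurrent regions."""
    cm = clone_map.reset_index(drop=True)
    event_rows = []
    chroms = cm["chromosome"].to_numpy()
    starts = cm["start"].to_numpy()
    ends = cm["end"].to_numpy()
    call_arr = calls.to_numpy(dtype=float)
    chrom_blocks = []
    for chrom in pd.unique(chroms):
        block = np.flatnonzero(chroms == chrom)
        chrom_blocks.append((chrom, block))
    for j, sample in enumerate(calls.columns):
        col = call_arr[:, j]
        for chrom, block in chrom_blocks:
            sub = col[block]
            for klass, pred in _CLASS_MASKS.items():
                with np.errstate(invalid="ignore"):
                    mask = np.where(np.isnan(sub), False, pred(sub))
                for s, e in _runs(mask):
                    gi, gj = block[s], block[e - 1]
                    event_rows.append(
                        (sample, chrom, int(starts[gi]), int(ends[gj]), klass, e - s,
                         int(gi), int(gj) + 1)
                    )
    events = pd.DataFrame(
        event_rows,
        columns=["sample_id", "chromosome", "start", "end", "class",
                 "n_probes", "start_index", "end_index"],
    )

    recurrent_rows = []
    n_samples = calls.shape[1]
    for klass, pred in _CLASS_MASKS.items():
        with np.errstate(invalid="ignore"):
            carrier = np.where(np.isnan(call_arr), False, pred(call_arr))
        for chrom, block in chrom_blocks:
            sub = carrier[block]  # clones x samples
            prev_key = None  # None marks "not inside a region"
            run_start = 0
            for t in range(len(block) + 1):
                key = tuple(np.flatnonzero(sub[t]).tolist()) if t < len(block) else None
                if key == ():
                    key = None
                if key != prev_key:
                    if prev_key is not None:
                        gi, gj = block[run_start], block[t - 1]
                        samples = [calls.columns[k] for k in prev_key]
                        recurrent_rows.append(
                            (chrom, int(starts[gi]), int(ends[gj]), klass,
                             len(samples), ",".join(map(str, samples)), n_samples)
                        )
                    run_start = t
                    prev_key = key
    recurrent = pd.DataFrame(
        recurrent_rows,
        columns=["chromosome", "start", "end", "class", "n_samples", "samples", "n_total"],
    )
    return EventCatalogue(events=events, recurrent=recurrent)


def frequency(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-clone fraction of non-missing samples gained (incl. amp) and lost (incl. homdel)."""
    arr = calls.to_numpy(dtype=float)
    present = ~np.isnan(arr)
    n = present.sum(axis=1)
    with np.errstate(invalid="ignore"):
        gained = (np.nan_to_num(arr, nan=0.0) >= GAIN).sum(axis=1).astype(float)
        lost = ((np.nan_to_num(arr, nan=0.0) <= LOSS) & present).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = pd.DataFrame(
            {
                "n_samples": n,
                "frac_gain": np.where(n > 0, gained / n, np.nan),
                "frac_loss": np.where(n > 0, lost / n, np.nan),
            },
            index=calls.index,
        )
    return out


def stratified_frequency(
    arm_calls: pd.DataFrame, clinical: pd.DataFrame, feature: str
) -> pd.DataFrame:
    """Per-group percentages of samples with each arm-level gain/loss call.

    ``feature`` names a clinical column; samples with a missing label are
    excluded from group denominators.
    """
    valid = [c for c in clinical.columns if c != "sample_id"]
    if feature not in valid:
        raise ValueError(f"unknown clinical feature {feature!r}; valid features: {valid}")
    labels = clinical.set_index("sample_id")[feature]
    labels = labels.reindex(arm_calls.columns)
    rows = []
    for group, members in labels.dropna().groupby(labels.dropna()).groups.items():
        sub = arm_calls.loc[:, list(members)]
        arr = sub.to_numpy(dtype=float)
        n = (~np.isnan(arr)).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct_gain = 100.0 * np.nansum(arr == GAIN, axis=1) / np.maximum(n, 1)
            pct_loss = 100.0 * np.nansum(arr == LOSS, axis=1) / np.maximum(n, 1)
        for arm, g, l, cnt in zip(arm_calls.index, pct_gain, pct_loss, n):
            rows.append((feature, group, arm, int(cnt), float(g), float(l)))
    return pd.DataFrame(
        rows, columns=["feature", "group", "arm", "n_samples", "pct_gain", "pct_loss"]
    )


class AberrationCaller(TransformerMixin, BaseEstimator):
    """Threshold-based ordinal aberration caller as a sklearn transformer.

    If ``normal_reference`` (probes x profiles of normal-vs-normal log2
    ratios) is given, ``fit`` derives the gain/loss cutoff as
    ``sd_multiplier`` x the average per-profile SD; otherwise the supplied
    or default thresholds are used verbatim.

    Parameters
    ----------
    thresholds : Thresholds, optional
    normal_reference : array-like, optional
    sd_multiplier : float, default 3.0

    Attributes
    ----------
    thresholds_ : Thresholds actually used after ``fit``.
    """

    def __init__(self, thresholds: Thresholds | None = None,
                 normal_reference=None, sd_multiplier: float = 3.0):
        self.thresholds = thresholds
        self.normal_reference = normal_reference
        self.sd_multiplier = sd_multiplier

    def fit(self, X, y=None):
        X = self._check(X)
        if self.normal_reference is not None:
            self.thresholds_ = derive_threshold(self.normal_reference, self.sd_multiplier)
        else:
            self.thresholds_ = self.thresholds or Thresholds()
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        """Map (n_samples, n_probes) log2 ratios to ordinal call codes."""
        if not hasattr(self, "thresholds_"):
            raise RuntimeError("AberrationCaller is not fitted")
        X = self._check(X)
        return _call_array(X, self.thresholds_)

    @staticmethod
    def _check(X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_probes)")
        return X
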