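"""Readers and writers for the on-disk artifacts of the pipeline.

Every tabular artifact is plain TSV with a header line and ``NA`` as the
missing-value token.  All coordinates are 0-based half-open throughout the
package; the BED writer emits them unchanged and any 1-based export would be
explicitly suffixed ``_1based`` (none exists today).

Artifacts
---------
clone map     : clone_id, chromosome, start, end, arm
ratio matrix  : probe_id + one column per sample, log2 ratios
clinical      : sample_id + clinical covariates
DE list       : expr_clone_id, gene_symbol, direction (up/down)
regions BED   : chrom, start, end, name (event class), score (sample count)
"""

from __future__ import annotations

import logging
import re
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NA_TOKEN = "NA"

CLONE_MAP_COLUMNS = ["clone_id", "chromosome", "start", "end", "arm"]
CLINICAL_FEATURES = [
    "stage",
    "lauren_type",
    "site",
    "differentiation",
    "hpylori",
    "ebv",
]

_CHROM_RE = re.compile(r"^(?:chr)?(\d+|[XYxy])$")


class FormatError(ValueError):
    """A file violated the documented dialect."""


def chromosome_sort_key(chrom: str) -> tuple[int, str]:
    """Natural chromosome order: 1..22 then X then Y, with/without 'chr'."""
    m = _CHROM_RE.match(str(chrom))
    if not m:
        raise FormatError(f"unsortable chromosome name: {chrom!r}")
    token = m.group(1).upper()
    if token.isdigit():
        return (int(token), "")
    return (1000 + {"X": 0, "Y": 1}[token], token)


def sort_clone_map(clone_map: pd.DataFrame) -> pd.DataFrame:
    order = sorted(
        range(len(clone_map)),
        key=lambda i: (
            chromosome_sort_key(clone_map["chromosome"].iat[i]),
            int(clone_map["start"].iat[i]),
        ),
    )
    return clone_map.iloc[order].reset_index(drop=True)


def validate_clone_map(clone_map: pd.DataFrame) -> pd.DataFrame:
    """Validate, sort and derive the midpoint ``position`` column."""
    missing = [c for c in CLONE_MAP_COLUMNS if c not in clone_map.columns]
    if missing:
        raise FormatError(f"clone map missing columns: {missing}")
    cm = clone_map.copy()
    if cm["clone_id"].duplicated().any():
        dups = cm.loc[cm["clone_id"].duplicated(), "clone_id"].tolist()[:5]
        raise FormatError(f"duplicate clone ids: {dups}")
    cm["start"] = cm["start"].astype(np.int64)
    cm["end"] = cm["end"].astype(np.int64)
    if (cm["start"] >= cm["end"]).any():
        raise FormatError("clone map rows with start >= end")
    bad_arm = ~cm["arm"].isin(["p", "q"])
    if bad_arm.any():
        raise FormatError(f"arm must be 'p' or 'q', got {cm.loc[bad_arm, 'arm'].unique()}")
    cm = sort_clone_map(cm)
    cm["position"] = (cm["start"] + cm["end"]) / 2.0
    return cm


def read_clone_map(path) -> pd.DataFrame:
    cm = pd.read_csv(path, sep="\t", dtype={"clone_id": str, "chromosome": str, "arm": str})
    return validate_clone_map(cm)


def write_clone_map(clone_map: pd.DataFrame, path) -> None:
    clone_map.loc[:, CLONE_MAP_COLUMNS].to_csv(path, sep="\t", index=False)


def validate_ratio_matrix(matrix: pd.DataFrame, clone_map: pd.DataFrame | None = None) -> pd.DataFrame:
    """Validate a probes x samples log2-ratio matrix, reordering to map order.

    Probes absent from the map are dropped (count logged); probes present in
    the map but absent from the matrix become all-missing rows so the matrix
    always aligns 1:1 with the map.
    """
    if matrix.index.duplicated().any():
        raise FormatError(f"duplicate probe ids: {matrix.index[matrix.index.duplicated()][:5].tolist()}")
    if matrix.shape[1] < 2:
        raise FormatError("at least 2 samples required")
    if pd.Index(matrix.columns).duplicated().any():
        raise FormatError("duplicate sample ids")
    values = matrix.astype(float)
    if np.isinf(values.to_numpy()).any():
        raise FormatError("ratio matrix contains non-finite (inf) values")
    if clone_map is not None:
        known = pd.Index(clone_map["clone_id"])
        extra = values.index.difference(known)
        if len(extra):
            logger.info("dropping %d probes not present in the clone map", len(extra))
        values = values.reindex(known)
        values.index.name = matrix.index.name or "probe_id"
    frac_missing = values.isna().mean(axis=1)
    n_sparse = int((frac_missing > 0.5).sum())
    if n_sparse:
        warnings.warn(f"{n_sparse} probes have >50% missing values (retained)", stacklevel=2)
    return values


def read_ratio_matrix(path, clone_map: pd.DataFrame | None = None) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_TOKEN])
    return validate_ratio_matrix(matrix, clone_map)


def write_ratio_matrix(matrix: pd.DataFrame, path) -> None:
    out = matrix.copy()
    out.index.name = out.index.name or "probe_id"
    out.to_csv(path, sep="\t", na_rep=NA_TOKEN, float_format="%.12g")


def read_clinical(path) -> pd.DataFrame:
    clin = pd.read_csv(path, sep="\t", dtype=str, na_values=[NA_TOKEN])
    if "sample_id" not in clin.columns:
        raise FormatError("clinical table requires a sample_id column")
    if clin["sample_id"].duplicated().any():
        raise FormatError("duplicate sample ids in clinical table")
    return clin


def write_clinical(clin: pd.DataFrame, path) -> None:
    clin.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)


def read_de_list(path) -> pd.DataFrame:
    de = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("expr_clone_id", "direction"):
        if col not in de.columns:
            raise FormatError(f"DE list missing column {col!r}")
    if de["expr_clone_id"].duplicated().any():
        raise FormatError("duplicate clone ids in DE list")
    bad = ~de["direction"].isin(["up", "down"])
    if bad.any():
        raise FormatError(f"DE direction must be up/down, got {de.loc[bad, 'direction'].unique()}")
    return de


def write_de_list(de: pd.DataFrame, path) -> None:
    de.to_csv(path, sep="\t", index=False)


BED_HEADER = "# chrom\tstart\tend\tname\tscore"


def write_regions_bed(regions: pd.DataFrame, path) -> None:
    """Serialize an event-region catalogue as 0-based half-open BED.

    ``name`` is the event class, ``score`` the number of samples carrying
    the event in the region.
    """
    required = {"chromosome", "start", "end", "class", "n_samples"}
    with open(path, "w") as fh:
        fh.write(BED_HEADER + "\n")
        if len(regions) == 0:
            return
        missing = required - set(regions.columns)
        if missing:
            raise FormatError(f"region table missing columns: {sorted(missing)}")
        if (regions["start"].astype(np.int64) >= regions["end"].astype(np.int64)).any():
            raise FormatError("region with start >= end")
        cols = zip(
            regions["chromosome"], regions["start"], regions["end"],
            regions["class"], regions["n_samples"],
        )
        for chrom, start, end, klass, count in cols:
            fh.write(f"{chrom}\t{int(start)}\t{int(end)}\t{klass}\t{int(count)}\n")


def read_regions_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, name, score = line.rstrip("\n").split("\t")
            rows.append((chrom, int(start), int(end), name, int(score)))
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "class", "n_samples"])
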