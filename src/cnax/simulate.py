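"""Synthetic aCGH and coupled expression data with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
BAC-clone genome tiled at ~1.5 Mb (23 chromosomes x ~102 clones ~ the 2353
clones of a desk-scale tumor panel), recurrent segmental aberrations planted
in seeded subsets of carrier samples, i.i.d. Gaussian clone-level noise on
the log2 ratios, uniformly planted missing values, and an expression matrix
in which a configurable fraction of cDNA clones is dosage-driven: their
expression equals ``dosage_effect`` times the true local copy-number log2
value at the nearest BAC clone plus independent noise, while the remaining
clones are pure noise.

Everything is reproducible: the same :class:`SimulationConfig` (including
``seed``) yields bit-identical matrices and ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calling import Thresholds, call_clones


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class AberrationEvent:
    """A planted segmental aberration.

    ``start_index``/``end_index`` are 0-based half-open clone indices within
    the chromosome; ``shift`` is the mean log2-ratio displacement and
    ``carrier_fraction`` the fraction of samples carrying the event.
    """

    chromosome: str
    start_index: int
    end_index: int
    shift: float
    carrier_fraction: float


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: int = 62
    n_chromosomes: int = 23
    clones_per_chrom: int = 102
    clone_spacing_bp: int = 1_500_000
    centromere_fraction: float = 0.4
    acgh_noise_sd: float = 0.075
    expr_noise_sd: float = 0.3
    missing_rate: float = 0.03
    aberration_spec: tuple[AberrationEvent, ...] | None = None
    n_expr_clones: int = 3000
    dosage_gene_fraction: float = 0.1
    dosage_effect: float = 1.0
    independent_de_fraction: float = 0.05
    admixture: float = 1.0  # shrink factor on planted shifts (non-tumor cell dilution)
    recurrence_min_fraction: float = 0.1  # carrier fraction making an event "recurrent"
    seed: int = 0

    def events(self) -> tuple[AberrationEvent, ...]:
        if self.aberration_spec is not None:
            return tuple(self.aberration_spec)
        return default_aberration_spec(self.n_chromosomes, self.clones_per_chrom)

    def validate(self) -> "SimulationConfig":
        if min(self.n_samples, self.n_chromosomes, self.clones_per_chrom) <= 0:
            raise ConfigurationError("sample/chromosome/clone counts must be positive")
        if self.clone_spacing_bp <= 0:
            raise ConfigurationError("clone_spacing_bp must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        if not 0 <= self.dosage_gene_fraction <= 1:
            raise ConfigurationError("dosage_gene_fraction must lie in [0, 1]")
        if not 0 < self.centromere_fraction < 1:
            raise ConfigurationError("centromere_fraction must lie in (0, 1)")
        valid_chroms = {f"chr{i + 1}" for i in range(self.n_chromosomes)}
        for ev in self.events():
            if ev.chromosome not in valid_chroms:
                raise ConfigurationError(f"event on unknown chromosome: {ev}")
            if not (0 <= ev.start_index < ev.end_index <= self.clones_per_chrom):
                raise ConfigurationError(f"event indices out of chromosome bounds: {ev}")
            if not 0 < ev.carrier_fraction <= 1:
                raise ConfigurationError(f"carrier_fraction outside (0, 1]: {ev}")
        return self


def default_aberration_spec(n_chromosomes: int, clones_per_chrom: int) -> tuple[AberrationEvent, ...]:
    """Recurrent gains/losses plus focal amplicons and homozygous deletions.

    Positions are expressed as fractions of the chromosome so the same
    pattern scales to small test genomes; the pattern mimics a tumor panel
    with broad arm-level gains (5p, 8q, 20pq), broad losses (4q, 9p, 18q,
    21q), focal high-level amplicons on 8q/20q and a focal deletion on 9p.
    """
    n = clones_per_chrom

    def span(lo_frac: float, hi_frac: float) -> tuple[int, int]:
        lo = int(math.floor(lo_frac * n))
        hi = max(lo + 1, int(math.ceil(hi_frac * n)))
        return lo, min(hi, n)

    raw = [
        ("chr5", 0.00, 0.40, +0.45, 0.35),
        ("chr8", 0.45, 1.00, +0.50, 0.40),
        ("chr8", 0.78, 0.84, +0.60, 0.10),   # focal amplicon stacked on 8q gain
        ("chr20", 0.00, 1.00, +0.45, 0.35),
        ("chr20", 0.58, 0.66, +0.65, 0.17),  # focal amplicon stacked on 20q gain
        ("chr4", 0.45, 1.00, -0.45, 0.30),
        ("chr9", 0.00, 0.40, -0.45, 0.30),
        ("chr9", 0.10, 0.14, -0.50, 0.11),   # focal deep deletion stacked on 9p loss
        ("chr18", 0.45, 1.00, -0.45, 0.30),
        ("chr21", 0.45, 1.00, -0.45, 0.25),
    ]
    events = []
    valid = {f"chr{i + 1}" for i in range(n_chromosomes)}
    for chrom, lo, hi, shift, frac in raw:
        if chrom not in valid:
            continue
        a, b = span(lo, hi)
        events.append(AberrationEvent(chrom, a, b, shift, frac))
    return tuple(events)


@dataclass
class GroundTruth:
    """Truth channel for parameter-recovery tests."""

    true_segment_means: pd.DataFrame
    true_calls: pd.DataFrame
    true_breakpoints: dict  # sample -> chromosome -> sorted clone indices (chromosome-local)
    event_carriers: list  # (AberrationEvent, list of sample ids)
    dosage_gene_ids: set = field(default_factory=set)
    dosage_bac_of: dict = field(default_factory=dict)  # expr_clone_id -> nearest BAC id
    de_labels: pd.Series | None = None


def make_clone_map(config: SimulationConfig) -> pd.DataFrame:
    """Evenly spaced BAC-like clones; arm split at ``centromere_fraction``."""
    config.validate()
    rows = []
    n = config.clones_per_chrom
    n_p = int(math.floor(config.centromere_fraction * n))
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        for i in range(n):
            start = i * config.clone_spacing_bp
            rows.append(
                (f"BAC_{chrom}_{i:04d}", chrom, start, start + config.clone_spacing_bp,
                 "p" if i < n_p else "q")
            )
    cm = pd.DataFrame(rows, columns=["clone_id", "chromosome", "start", "end", "arm"])
    cm["position"] = (cm["start"] + cm["end"]) / 2.0
    return cm


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, stream]))


def simulate_acgh(clone_map: pd.DataFrame, config: SimulationConfig,
                  thresholds: Thresholds | None = None):
    """Simulate the aCGH log2-ratio matrix and its ground truth."""
    config.validate()
    th = thresholds or Thresholds()
    samples = [f"T{k + 1:03d}" for k in range(config.n_samples)]
    n_probes = len(clone_map)
    index = pd.Index(clone_map["clone_id"], name="probe_id")
    mean = np.zeros((n_probes, config.n_samples))
    chroms = clone_map["chromosome"].to_numpy()
    chrom_offset = {}
    for chrom in pd.unique(chroms):
        chrom_offset[chrom] = int(np.flatnonzero(chroms == chrom)[0])

    carrier_rng = _rng(config, 1)
    event_carriers = []
    for ev in config.events():
        if ev.chromosome not in chrom_offset:
            raise ConfigurationError(f"event outside the clone map: {ev}")
        n_carriers = int(round(ev.carrier_fraction * config.n_samples))
        carriers = np.sort(carrier_rng.choice(config.n_samples, size=n_carriers, replace=False))
        off = chrom_offset[ev.chromosome]
        if carriers.size:
            row_idx = np.arange(off + ev.start_index, off + ev.end_index)
            mean[np.ix_(row_idx, carriers)] += ev.shift * config.admixture
        event_carriers.append((ev, [samples[k] for k in carriers]))

    noise_rng = _rng(config, 2)
    data = mean + noise_rng.normal(0.0, config.acgh_noise_sd, size=mean.shape)
    if config.missing_rate > 0:
        miss_rng = _rng(config, 3)
        data[miss_rng.random(size=data.shape) < config.missing_rate] = np.nan

    true_means = pd.DataFrame(mean, index=index, columns=samples)
    true_calls = call_clones(true_means, th)
    breakpoints: dict = {}
    for j, sample in enumerate(samples):
        breakpoints[sample] = {}
        for chrom in pd.unique(chroms):
            block = np.flatnonzero(chroms == chrom)
            mu = mean[block, j]
            bps = (np.flatnonzero(np.diff(mu) != 0) + 1).tolist()
            breakpoints[sample][chrom] = bps
    truth = GroundTruth(
        true_segment_means=true_means,
        true_calls=true_calls,
        true_breakpoints=breakpoints,
        event_carriers=event_carriers,
    )
    matrix = pd.DataFrame(data, index=index, columns=samples)
    return matrix, truth


def make_expression_map(config: SimulationConfig) -> pd.DataFrame:
    """cDNA clone positions drawn uniformly within the aCGH genome."""
    config.validate()
    rng = _rng(config, 4)
    chrom_len = config.clones_per_chrom * config.clone_spacing_bp
    chrom_idx = rng.integers(0, config.n_chromosomes, size=config.n_expr_clones)
    pos = rng.integers(0, chrom_len - 1000, size=config.n_expr_clones)
    order = np.lexsort((pos, chrom_idx))
    rows = []
    n_p_end = int(math.floor(config.centromere_fraction * config.clones_per_chrom)) * config.clone_spacing_bp
    for k, o in enumerate(order):
        chrom = f"chr{chrom_idx[o] + 1}"
        start = int(pos[o])
        rows.append(
            (f"EXPR_{k:05d}", f"GENE{k:05d}", chrom, start, start + 1000,
             "p" if start + 500 < n_p_end else "q")
        )
    em = pd.DataFrame(rows, columns=["clone_id", "gene_symbol", "chromosome", "start", "end", "arm"])
    em["position"] = (em["start"] + em["end"]) / 2.0
    return em


def expected_dosage_correlation(shift: float, carrier_fraction: float,
                                dosage_effect: float, expr_noise_sd: float,
                                cn_noise_var: float = 0.0) -> float:
    """Closed-form Pearson correlation for a single-event dosage gene.

    The copy-number signal is Bernoulli(carrier_fraction) x shift, so its
    variance is f(1-f) shift^2; expression adds independent noise with SD
    ``expr_noise_sd`` on top of ``dosage_effect`` x signal, and the measured
    copy-number value carries ``cn_noise_var`` of residual noise (0 for the
    noiseless true segment means).
    """
    v = carrier_fraction * (1 - carrier_fraction) * shift * shift
    num = dosage_effect * v
    den = math.sqrt((dosage_effect**2 * v + expr_noise_sd**2) * (v + cn_noise_var))
    return num / den if den > 0 else 0.0


def dosage_effect_for_target_r(r: float, shift: float, carrier_fraction: float,
                               expr_noise_sd: float, cn_noise_var: float = 0.0) -> float:
    """Invert :func:`expected_dosage_correlation` for the effect slope."""
    v = carrier_fraction * (1 - carrier_fraction) * shift * shift
    w = v + cn_noise_var
    denom = v * (v - r * r * w)
    if denom <= 0:
        raise ValueError("target correlation not attainable with these variance components")
    return math.sqrt(r * r * expr_noise_sd**2 * w / denom)


def simulate_expression(expr_map: pd.DataFrame, acgh_map: pd.DataFrame,
                        truth: GroundTruth, config: SimulationConfig):
    """Simulate expression log-ratios coupled to the aCGH ground truth.

    Dosage genes read the *noiseless* true segment mean at their nearest BAC
    clone, keeping the variance decomposition exact; DE labels mark dosage
    genes under recurrent gains as 'up' and under recurrent losses as
    'down', plus a copy-number-independent DE fraction.
    """
    config.validate()
    n_expr = len(expr_map)
    samples = list(truth.true_segment_means.columns)
    rng = _rng(config, 5)

    # nearest BAC per expression clone, same chromosome
    acgh_pos = acgh_map["position"].to_numpy()
    acgh_chrom = acgh_map["chromosome"].to_numpy()
    bac_ids = acgh_map["clone_id"].to_numpy()
    nearest = np.empty(n_expr, dtype=int)
    for chrom in pd.unique(expr_map["chromosome"]):
        block = np.flatnonzero(acgh_chrom == chrom)
        if block.size == 0:
            raise ConfigurationError(f"expression clones on {chrom} outside the aCGH genome")
        e_rows = np.flatnonzero(expr_map["chromosome"].to_numpy() == chrom)
        epos = expr_map["position"].to_numpy()[e_rows]
        k = np.searchsorted(acgh_pos[block], epos)
        k = np.clip(k, 1, block.size - 1) if block.size > 1 else np.zeros(e_rows.size, int)
        left = np.abs(acgh_pos[block][np.maximum(k - 1, 0)] - epos)
        right = np.abs(acgh_pos[block][np.minimum(k, block.size - 1)] - epos)
        choice = np.where(left <= right, np.maximum(k - 1, 0), np.minimum(k, block.size - 1))
        nearest[e_rows] = block[choice]

    n_dosage = int(round(config.dosage_gene_fraction * n_expr))
    dosage_idx = np.sort(rng.choice(n_expr, size=n_dosage, replace=False))
    dosage_mask = np.zeros(n_expr, dtype=bool)
    dosage_mask[dosage_idx] = True

    mu = truth.true_segment_means.to_numpy()
    expr_mean = np.zeros((n_expr, len(samples)))
    expr_mean[dosage_idx] = config.dosage_effect * mu[nearest[dosage_idx]]
    data = expr_mean + rng.normal(0.0, config.expr_noise_sd, size=expr_mean.shape)
    if config.missing_rate > 0:
        data[rng.random(size=data.shape) < config.missing_rate] = np.nan

    # DE labels
    n_samples = len(samples)
    min_carriers = max(1, int(round(config.recurrence_min_fraction * n_samples)))
    labels = np.array(["none"] * n_expr, dtype=object)
    for g in dosage_idx:
        col = mu[nearest[g]]
        if (col > 0).sum() >= min_carriers:
            labels[g] = "up"
        elif (col < 0).sum() >= min_carriers:
            labels[g] = "down"
    non_dosage = np.flatnonzero(~dosage_mask)
    n_indep = int(round(config.independent_de_fraction * n_expr))
    if n_indep and non_dosage.size:
        chosen = rng.choice(non_dosage, size=min(n_indep, non_dosage.size), replace=False)
        labels[chosen] = rng.choice(["up", "down"], size=chosen.size)

    index = pd.Index(expr_map["clone_id"], name="probe_id")
    matrix = pd.DataFrame(data, index=index, columns=samples)
    truth.dosage_gene_ids = set(expr_map["clone_id"].to_numpy()[dosage_idx])
    truth.dosage_bac_of = {
        expr_map["clone_id"].iat[g]: bac_ids[nearest[g]] for g in dosage_idx
    }
    truth.de_labels = pd.Series(labels, index=index, name="de_label")
    return matrix, truth


def de_list_from_truth(expr_map: pd.DataFrame, truth: GroundTruth) -> pd.DataFrame:
    """Materialize the differential-expression list the candidate filter consumes."""
    labels = truth.de_labels
    keep = labels[labels.isin(["up", "down"])]
    em = expr_map.set_index("clone_id")
    return pd.DataFrame(
        {
            "expr_clone_id": keep.index,
            "gene_symbol": em.loc[keep.index, "gene_symbol"].to_numpy(),
            "direction": keep.to_numpy(),
        }
    )


def simulate_clinical(config: SimulationConfig) -> pd.DataFrame:
    """Arbitrary grouping factors shaped like the clinical annotation table."""
    rng = _rng(config, 6)
    samples = [f"T{k + 1:03d}" for k in range(config.n_samples)]
    return pd.DataFrame(
        {
            "sample_id": samples,
            "stage": rng.choice(["1", "2", "3", "4"], size=config.n_samples),
            "lauren_type": rng.choice(
                ["intestinal", "diffuse", "mixed", "indeterminate"],
                size=config.n_samples, p=[0.45, 0.4, 0.1, 0.05],
            ),
            "site": rng.choice(["antrum", "body", "cardia"], size=config.n_samples),
            "differentiation": rng.choice(["well_moderate", "poor"], size=config.n_samples),
            "hpylori": rng.choice(["pos", "neg"], size=config.n_samples),
            "ebv": rng.choice(["pos", "neg"], size=config.n_samples, p=[0.1, 0.9]),
        }
    )


def simulate_all(config: SimulationConfig):
    """Run the full generator; returns (acgh_map, acgh, expr_map, expr, clinical, de, truth)."""
    acgh_map = make_clone_map(config)
    acgh, truth = simulate_acgh(acgh_map, config)
    expr_map = make_expression_map(config)
    expr, truth = simulate_expression(expr_map, acgh_map, truth, config)
    clinical = simulate_clinical(config)
    de = de_list_from_truth(expr_map, truth)
    return acgh_map, acgh, expr_map, expr, clinical, de, truth


def truth_table(truth: GroundTruth, thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Planted events as a flat table (sample, chrom, clone span, shift, call).

    The call column classifies each event's own shift with the standard
    thresholds (stacked events may call higher at overlapping clones).
    """
    from .calling import CALL_LABELS

    th = thresholds or Thresholds()
    rows = []
    for ev, carriers in truth.event_carriers:
        call = CALL_LABELS[int(call_clones(np.array([[ev.shift]]), th)[0, 0])]
        for s in carriers:
            rows.append((s, ev.chromosome, ev.start_index, ev.end_index, ev.shift, call))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "chromosome", "start_clone", "end_clone", "shift", "call"],
    )
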