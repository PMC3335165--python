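# Methods

`cnax` reconstructs, as a reusable and fully tested pipeline, the
integrative analysis of tumor DNA copy-number profiles (two-color BAC array
CGH log2 ratios) and matched cDNA expression arrays: segmentation of the
copy-number signal, ordinal aberration calling, per-clone copy-number /
expression dosage correlation with a permutation null and FDR control, and
a three-criterion filter nominating candidate oncogenes and tumor
suppressor genes. This note records the models, the parameters that matter,
the numerical choices made where the design was genuinely open, and what
the synthetic-data experiments do and do not establish.

## Copy-number model and segmentation

Each sample's profile is a sequence of per-clone log2(tumor/reference)
ratios ordered along the genome, modeled as piecewise constant plus noise.
Chromosomes are segmented independently with circular binary segmentation
(CBS): the current stretch of clones is treated as a circle; every circular
split — an unordered boundary pair (i, j), each group at least 2 clones —
is scored with the classical pooled-variance two-sample t-statistic

    T(i,j) = |m_arc − m_comp| / sqrt( s²·(1/n_arc + 1/n_comp) ),
    s² = (SS_arc + SS_comp) / (n − 2),

and the maximal |T| is referred to a permutation distribution: the stretch
is shuffled B times and p is the plain proportion of shuffles whose maximal
arc statistic reaches the observed one. If p ≤ α the boundaries become
change points and the pieces are segmented recursively; afterwards adjacent
segments whose means differ by less than `merge_tol` are merged.

Defaults: α = 0.01, B = 1000 (B < 100 rejected), `merge_tol` = 0.05 log2
units — all configurable.

Numerical/design choices:

- **Pooled rather than per-group variance.** With per-group (Welch)
  variances, a width-1 arc makes the maximal statistic a function of the
  value multiset only — identical for every shuffle, so no split is ever
  significant — and width-2 arcs of coincidentally close neighbours have
  near-zero within-arc variance and dominate the permutation null,
  collapsing power. Pooling the variance over both groups (the statistic of
  the original CBS formulation) removes both pathologies; breakpoint
  recovery under the conditions of the recovery experiment below is ~100%.
  Both the arc and its complement must contain at least 2 clones; isolated
  single-clone excursions are the outlier smoother's responsibility.
- **Canonical arc enumeration.** Boundary pairs are enumerated once
  (0 ≤ i < j ≤ n−1); the arc (j, n] duplicates the complement of (0, j] and
  would make the arg-max tie-break depend on floating-point rounding. Ties
  are broken by smaller start index, then shorter arc. After centering,
  maximizing T² is algebraically equivalent to maximizing
  (1/n_arc + 1/n_comp)·(arc sum)², which is what the vectorized scan
  computes; an exhaustive independent implementation serves as the oracle
  in the tests.
- **Path-independent permutation streams.** The permutation RNG for a
  tested stretch is seeded from (global seed, sample, chromosome, stretch
  start, stretch end), so its p-value does not depend on the recursion path.
  A consequence worth having: the set of accepted splits is monotone in α,
  so lowering α can only reduce the number of segments. Permutation
  generation stops early only when the exceedance count already certifies
  p > α; decisions are always identical to the full-B decisions, and fixed
  seeds give bit-identical segmentations.
- **Outlier smoothing before testing.** A clone is flagged when it deviates
  from the medians of *both* its left-side and right-side windows of up to
  k non-missing neighbours (self excluded) by more than z robust SDs of the
  chromosome (1.4826 × MAD); flagged values are shrunk to the ±k neighbour
  median ± z·SD for change-point testing only. Requiring both sides keeps
  the first clone of a genuine step — which agrees perfectly with its own
  side — from being mistaken for an outlier, while isolated spikes and
  adjacent double spikes (k = 2) are caught. Defaults k = 2, z = 4.
- **Missing values** are removed before index arithmetic and re-inserted
  afterwards. The reported "smoothed" matrix holds the segment mean at
  ordinary clones, the originally observed ratio at flagged outlier clones,
  and the segment mean at missing clones whose midpoint falls inside a
  segment's genomic span; clones outside every segment (all-missing
  chromosome ends) stay missing. Sequences with fewer than 4 observed
  clones form a single segment.

## Aberration calling

Per-clone calls are ordinal — homozygous deletion < loss < neutral < gain <
amplification — by strict thresholding of the **raw** log2 ratio: gain
> 0.225, loss < −0.225, amplification > 0.8, homozygous deletion < −0.7.
A value exactly at a cutoff stays in the more neutral class. The ±0.225
clone-level cutoff is 3 × the average per-profile SD of normal-vs-normal
hybridizations and can be re-derived from a supplied reference matrix
(`derive_threshold`); the focal cutoffs are configured independently. Arm
calls use the median log2 ratio of all clones on the arm against the same
±0.225. Smoothed values are reserved for the correlation analysis; a caller
can be applied to them for sensitivity checks since calling is a pure
function of its input matrix.

Events are maximal runs of same-class calls, counted separately per run.
Gain runs merge gain and amplification clones (an amplification is also
reported as its own focal event nested in the enclosing gain run); losses
symmetrically enclose homozygous deletions. Recurrent regions are maximal
clone intervals with a constant, non-empty carrier set per class, reported
with sample counts (the `12/72`-style summaries). Frequencies count
amplification within gain and homozygous deletion within loss; stratified
frequencies report per-group percentages of arm-level calls, excluding
samples with a missing clinical label from the denominators.

## Dosage correlation with a permutation null

Each expression clone is mapped to the copy-number clone within 1 Mb
(midpoint to midpoint) maximizing the Pearson correlation between the
clone's expression and the CBS-smoothed copy number over pairwise-complete
shared samples (≥ `min_n` = 10, else the candidate is skipped); ties break
by smaller distance, then lexicographic id. Clones without a usable
candidate are marked unmapped and excluded downstream; if *no* clone has a
candidate the maps are presumed to be on different assemblies and the run
aborts.

Significance: B = 1000 global shuffles of the expression sample labels, one
shuffle per replicate shared by all clones (preserving between-clone
dependence, which an honest FDR requires); per clone, r is recomputed
against the already-chosen partner and p is the one-sided plain proportion
of shuffles with permuted r ≥ observed r. p = 0 is reported as 0; a
(k+1)/(B+1) estimator is available (`pseudo_count`). Shuffles do not
re-select the best partner by default — selection is part of the fixed
mapping; the more conservative variant that re-chooses the best 1-Mb
candidate under every shuffle is available (`reselect`), as is two-sided
scanning on |r| (`scan_negative`). Benjamini–Hochberg adjustment
(statsmodels' step-up, validated against a brute-force implementation) maps
p to q, and clones with r > 0.29 and q < 0.01 are selected; the largest q
among the selected is reported as the achieved FDR bound.

The 20-Mb binned map divides every chromosome arm into bins (a short arm is
one bin), computes all pairwise Pearson correlations between expression
clones in one bin and copy-number clones in another (missing sample values
mean-imputed per clone before standardizing), and averages them per bin
pair. Coupled data elevate the diagonal (same-bin) entries relative to
off-diagonal pairs; the medians of both groups summarize the contrast.

## Candidate nomination

A selected clone becomes a candidate oncogene when its mapped copy-number
clone shows at least 5 more gain-or-amp calls than loss-or-homdel calls
across samples *and* the clone is up-regulated in tumors per the supplied
differential-expression list; a candidate tumor suppressor in the mirrored
case. Discordant clones (e.g. gained but down-regulated) are excluded and
logged. Imbalance is counted on raw-ratio calls, consistent with the
calling convention, and per clone (the filter operates on the clone-level
selection). Gene roll-up keeps one representative clone per gene (largest
r); genes whose clones disagree on the class are reported as conflicts and
left out of the roll-up rather than silently collapsed. Candidate
expression patterns are clustered (samples and clones) under
1 − centered-Pearson distance with average linkage; constant rows are
dropped, and a single-candidate matrix falls back to Euclidean distance
for the sample dendrogram (centered correlation is undefined on length-1
profiles).

## Synthetic data generator

The generator emulates the data structure the analysis assumes, with a full
truth channel. Defaults model the study scale: 62 samples, 23 chromosomes ×
102 clones at 1.5 Mb spacing (≈ 2346 clones, matching a ~2353-clone 1.5-Mb
BAC array), arm split at a 0.4 centromere fraction, clone-level i.i.d.
Gaussian noise with SD 0.075 — chosen so the 3×SD rule reproduces the 0.225
cutoff; the arrays' true noise is not published — missing values planted
uniformly at 3%, and 3000 expression clones placed uniformly with
expression noise SD 0.3. Aberrations are planted as (chromosome, clone
span, mean shift, carrier fraction) events with carriers drawn without
replacement; the default panel mimics recurrent gains (5p, 8q, 20pq with
focal amplicons on 8q/20q) and losses (4q, 9p with a focal deep deletion,
18q, 21q) at carrier fractions 0.10–0.40. An optional admixture factor
shrinks all shifts to model contamination by non-tumor cells.

Dosage-responsive expression clones (default fraction 0.1) read
`dosage_effect` × the *noiseless* true segment mean at their nearest
copy-number clone, plus noise; this keeps the closed-form correlation

    r = β·v / sqrt( (β²·v + σ_e²) · (v + σ_c²) ),   v = f(1−f)·Δ²

exact (β slope, Δ shift, f carrier fraction, σ_e expression noise, σ_c
residual copy-number noise), and `dosage_effect_for_target_r` inverts it.
Differential-expression labels are "up" for dosage clones under a recurrent
gain, "down" under a recurrent loss (recurrence = ≥ 10% carriers), plus a
copy-number-independent DE fraction (default 5%). Identical configurations
are bit-identical, including the on-disk TSVs.

What the generator does **not** model: dye bias, spatial artifacts, GC
waves, segment-length distributions of real genomes, linkage between
clinical covariates and genotype (clinical labels are arbitrary grouping
factors). Passing tests therefore demonstrate correctness of the
*algorithms* under the stated statistical assumptions, not performance on
any particular real array platform.

## Calibration experiments and problem sizes

The experiments in `cnax.validation` (run both by the test suite and by
`scripts/acceptance.py`) use these fixed conditions, chosen as desk-scale
versions of the study design:

- **Threshold recovery**: 3 normal-vs-normal profiles × 2300 clones at
  true SD 0.075; the derived gain cutoff lands within 0.225 ± 0.01.
- **Breakpoint recovery**: 50 simulated chromosomes of 200 clones with
  breakpoints at 60/140 (|shift| 0.5, noise SD 0.15, α 0.01, B 1000);
  recovery within ±2 clones, plus 200 flat null chromosomes for the
  false-split rate (compared with the binomial band at α).
- **Null calibration**: 500 independent expression/copy-number clone pairs
  over 62 samples, B = 1000; tail mass at 0.05 and KS distance to uniform.
  The KS statistic on 500 p-values has sampling noise of ~0.04–0.06 even
  under perfect uniformity, so single-seed values near 0.05 are expected.
- **FDR and power**: 20 replicates of a mixture with every chromosome
  aberrant (Δ 0.6 in half the samples) and 10% dosage clones, the slope set
  by the closed form so true r ≈ 0.6; empirical FDR and sensitivity of the
  r > 0.29 & q < 0.01 selection.
- **Diagonal contrast**: 20 replicates with genome-wide arm-scale CN
  variability and a 25% dosage-responsive fraction — the genome-wide
  dosage structure such panels show — against a decoupled twin (slope 0).
  A configuration leaving much of the genome copy-number-invariant would
  dilute the diagonal median toward 0 for reasons unrelated to the method.
- **End-to-end**: the full default study (62 × 2346 aCGH, 3000 expression
  clones, B = 1000 for both permutation layers) runs in well under a minute
  per stage on one CPU; a re-run with the same seeds is byte-identical.

## Known limitations

- CBS here is the plain recursive permutation scheme; no hybrid tail
  approximation, no undo-splits pruning beyond mean-merging, no
  multi-sample joint segmentation.
- Recurrent regions are a deterministic carrier-set catalogue, not a
  significance-tested recurrence analysis; no ploidy or purity correction.
- Correlation records stay at clone level; the gene roll-up is a reporting
  convenience, not a statistical aggregation of multi-clone genes.
- Real-data users must supply clone maps on a single assembly; no liftover
  is performed.
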