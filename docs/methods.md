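# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `mirlink`.

## Differential expression (`mirlink.de`)

Counts K_fs for feature f in sample s are modelled as negative binomial
with mean s_s·q_fs and dispersion α_f (Var = μ + αμ²).

**Size factors.** Median-of-ratios: for every feature positive in all
samples, the ratio of its count to its across-sample geometric mean is
formed; the sample's factor is the median ratio. The factors are reported
exactly as the median step yields them — their geometric mean is 1 only up
to the estimator's own sampling scale, and no renormalization is applied,
so downstream quantities are invariant to the common scale anyway.

**Dispersion.** A method-of-moments estimate per feature uses the pooled
within-group variance of normalized counts. Estimates are shrunk in log
space toward a parametric trend α(μ) = a₀ + a₁/μ fitted to binned medians
(20 log-mean bins, least squares, coefficients floored at 0), with a prior
weight of 4 pseudo-degrees of freedom, and then floored at the trend. The
floor is deliberate: with 5 residual degrees of freedom (4+3 samples),
moment estimates scatter far below the truth half the time, and letting
them pull the dispersion down makes the Wald test sharply anti-conservative.
With the floor, the null false-positive rate at p < 0.05 sits at ~0.05
(measured by the test suite and the acceptance script on 2,000-feature
null simulations).

**Test.** The two-group NB GLM log μ = offset + β₀ + β₁x (x = ±½) is fitted
by vectorized IRLS with the log size factors as offsets; β₁/ln 2 is the
reported log2 fold change of the first group over the second. The Wald
statistic β₁/SE(β₁) is referred to a standard normal, two-sided.
Coefficients are bounded at ±30 (natural log) so an all-zero group yields a
large-but-finite estimate with a large SE rather than a divergence.
Features whose normalized counts are identical in every sample are reported
as log2FC = 0, stat = 0, p = 1 exactly; features with equal group means get
log2FC = 0. Features with mean normalized count below 0.5 keep their
p-value but are excluded from BH adjustment (padj = NaN), an independent
low-count filter. BH adjustment is the plain step-up procedure.

**Screen thresholds.** `filter_de` retains |log2FC| > 0.5 AND adjusted
p < 0.05, both strict, defaulting to the adjusted p (a raw-p switch
exists). Strictness at the boundary is part of the contract and is tested.

Not implemented by design: multi-factor designs, outlier-count
replacement, and posterior (apeglm-style) fold-change shrinkage. This is a
DESeq2-like engine, not a bit-exact clone.

## Pre-ranked GSEA (`mirlink.gsea`)

Ranking defaults to signed log2FC, descending, with ties broken by
lexicographic feature ID (deterministic and input-order independent); |log2FC|
and the Wald statistic are available as alternatives. Signed ranking is
the default because up- and down-regulated set enrichment are reported
separately downstream.

ES is the signed extremum of the weighted KS running sum with weight
p = 1: hits add |score|/Σ|score over hits|, misses subtract 1/(N−N_hits).
When the positive and negative extrema tie exactly, the positive one is
taken (the same rule in both the full-profile and the fast hit-position
implementation, with a 1e-12 tolerance, so antisymmetry under score
negation holds everywhere except exact ties). If every member score is
zero, hit increments fall back to equal weights.

The null distribution draws `n_perm` uniform same-size gene sets (gene
permutation; with 3–4 samples per group a phenotype permutation null is
not meaningful). Null draws are cached per set size and shared across
sets. p = (b+1)/(m+1) within the same-sign half of the null; NES divides
ES by the mean |null ES| of matching sign; BH is applied across reported
sets. Defaults: n_perm = 10,000, set-size bounds [5, 500], all declared
choices (the upstream publication states none of them). The leading edge
is the set members at or before the running-sum extremum (at or after, for
negative ES).

An enumeration oracle (all C(N, k) same-size sets at N ≤ 8) verifies the
permutation estimate in the tests.

## Interactome screen (`mirlink.interactome`)

Expression is log2(count/size-factor + 1); the transform is a declared
choice. If median-of-ratios is undefined (no all-positive feature), the
screen falls back to total-count factors rescaled to geometric mean 1,
with a warning.

Pearson r is computed for every supplied miRNA × gene pair (the standard
screen passes the DE miRNAs against all genes); p comes from the t
transform with n−2 degrees of freedom. Zero-variance features yield
flagged records with r = NaN that can never pass the filter. The screen
keeps r < −0.7 AND p < 0.05, strict. No multiplicity correction is applied
to the screen (the published procedure filters on raw p plus the r bound);
a BH column is reported alongside for transparency.

**Scope.** The default correlates across the pooled samples (n = 7 in the
reference design). Per-group scopes are exposed but at n = 3 the p < 0.05
gate requires |r| > 0.997, which makes a per-group screen essentially
unusable; pooled is therefore the operative default, and per-group results
are reported separately, never mixed.

**Evidence merge.** Pairs are matched case-insensitively on the miRNA
mature accession or ID and the gene symbol. An edge is kept when the pair
has validated evidence (TarBase/miRTarbase) or predictions from at least
`min_predicted_dbs` distinct prediction databases (DIANA-microT, ElMMo,
PITA). The default threshold is 1 with a validated bypass, because the
packaged published evidence table itself contains single-database
(ElMMo-only) pairs; the stricter ≥3-database rule is available by
configuration. Duplicate pairs collapse into one network edge with merged
evidence; node direction attributes (up/down) come from the DE tables,
with 'unknown' plus a warning for features absent from them.

## Cohort statistics (`mirlink.cohort`)

ROUT outlier detection is specialized to the constant model: residuals
from the median, RSDR = 68.27th percentile of |residuals| × n/(n−1),
two-tailed t tail probabilities with n−1 degrees of freedom, and an
FDR step-up at rate Q flagging the most extreme points. Q defaults to 1%.
Zero RSDR or n < 3 performs no detection.

Continuous comparisons from raw data use a Shapiro–Wilk gate at α = 0.05
per group: pooled-variance Student t if both groups pass, Mann–Whitney
otherwise (exact for group sizes ≤ 8, tie-corrected normal approximation
above). From printed (mean, SD, n) summaries only the pooled-variance t is
computable. Pooled variance (not Welch) is used because it reproduces the
published continuous baseline p-values.

Categorical rows use the uncorrected Pearson chi-square on counts
reconstructed as round(percent/100 × n). This choice reproduces the
published Aspirin (0.003), Diabetes (0.519), and Diuretics (0.757) rows;
three published rows (Sex, high blood pressure, dyslipidemia) match
neither chi-square (with or without continuity correction) nor Fisher on
any reconstructable counts and are flagged via `matches_printed=False`
rather than forced. Two further published values differ in the third
decimal (LVESD prints 0.969 vs computed 0.9685; Diuretics 0.757 vs
0.7565) because the printed summary inputs are themselves rounded; the
package reports the computed values.

## Quantification (`mirlink.quant`)

2^−ΔΔCt: ΔCt = Ct_target − arithmetic mean of the reference Cts (the
standard multi-reference convention, equal to geometric-mean normalization
of expression), ΔΔCt relative to the calibrator-group mean, fold =
2^−ΔΔCt. The group test runs on ΔCt values through the normality-gated
comparison above. No amplification-efficiency correction. When two
reference assays are listed (e.g. GAPDH + ACTB, or U6 + 5S), both are
combined by the mean; using whichever single reference passed QC is a
caller decision, not a package default.

Luciferase analysis: activity = experimental/control luminescence per
well, rescaled to baseline mean 1, two-sided Student t per condition
against the baseline. Controls must be positive and conditions measured at
least in triplicate.

## Synthetic cohorts (`mirlink.simulate`)

The generator emulates the reference study design: group sizes default to
4 + 3 (the paired-profile subset), NB counts with a single dispersion
α = 0.05, library sizes log-uniform over [0.8M, 1.2M] (a scaled-down
stand-in for sequencing depth spread; relative abundances are log-normal
with σ = 2 log2 units), planted effect magnitudes uniform in [2.0, 2.5]
log2 units (well above the 0.5 screen threshold — the scale of effect the
screen is designed to catch), 60/2000 DE genes and 5/200 DE miRNAs, and 4
repressive couplings with slope −1.5.

**Coupling mechanism.** A coupled target's log2 mean is shifted by
coupling_strength × the miRNA's per-sample log2 deviation, where that
deviation comprises the miRNA's planted group effect plus a latent
N(0, 0.4²) per-sample term. Both differential expression and negative
correlation therefore arise from a single mechanism. The design point
matters: at n = 7, the screen needs r < −0.754; driving that reliably with
a latent term alone requires so much within-group miRNA variance that the
miRNA's own DE test fails at 4 vs 3 — routing the group effect through the
coupling gives planted pairs r ≈ −0.95 from group separation while keeping
within-group dispersion compatible with DE detection. The latent SD of 0.4
adds sample-level individuality without destroying either property.

**Decoys.** Evidence fixtures embed every planted pair plus `n_decoys`
decoy rows: 95% reference miRNAs outside the DE panel (as real target
databases are dominated by rows irrelevant to any given contrast, and
these exercise the DE/universe gate), 5% pair a DE miRNA with an uncoupled
non-DE gene, exercising the correlation gate under the null, where each
such decoy passes by chance with probability ≈ 2.5% at n = 7. Decoy and
planted sets are disjoint by construction, so evidence-filtering tests are
non-circular.

**What the generator does not model:** read-level artifacts (FASTQ),
batch/lane effects, isomiR structure, donor pairing, gene–gene
correlation beyond the planted couplings, and realistic library sizes
(scaled down for test-suite speed; the DE and correlation operating
characteristics depend on counts per feature, which the defaults keep in a
realistic 10²–10³ range). Passing tests therefore demonstrate the
pipeline's correctness and its operating characteristics under the stated
generative model, not performance on any real cohort.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the recovery study at
1,000 genes × 100 miRNAs over 50 seeds, null calibration at 2,000 features
× 3 seeds, and the enumeration oracle at N = 8; these sizes give stable
estimates (binomial SE ≈ 3–5% on the recovery rate) while keeping the
whole suite around ten seconds.

## Known limitations

- The Wald normal reference is approximate at 3–4 samples per group; the
  dispersion floor trades a little power for calibration.
- The pooled-scope correlation conflates between-group and within-group
  covariation; that is intrinsic to screening at n = 7 and is why the
  evidence intersection and downstream experimental validation exist.
- ROUT here is the constant-model specialization, not the full
  robust-regression version.
- The per-group correlation scope is exposed for completeness but is
  underpowered at these group sizes (see above).
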