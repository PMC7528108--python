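# Methods

This note documents the statistical procedures qtlkit implements, the
choices made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the numerical details that affect
results.

## cis-eQTL mapping

For each gene, every expression feature (exon or gene quantification) is
tested against every variant with MAF above the threshold (default 0.01;
0.05 is conventional for small sorted-cell cohorts) within ±1 Mb of the
canonical TSS. The model is OLS of expression on dosage plus covariates;
slopes, standard errors and two-sided t-tests use n − k − 2 degrees of
freedom (k = number of covariates). Implementation residualizes both
expression and dosage on the covariates once (Frisch–Waugh–Lovell), which
reproduces the full-design OLS slope exactly and lets the scan run as one
correlation matrix product per gene. Variants whose dosage is numerically
collinear with the covariates (residual variance < 1e-10 of the raw
variance) are excluded from the scan rather than reported with unstable
estimates.

**Permutation calibration.** Expression sample labels are permuted jointly
across the gene's features (so the exon-grouping multiplicity is absorbed
by the permutation scheme), genotypes and covariates stay fixed, and the
minimum nominal p over all feature × variant pairs is recorded per
permutation. Because all pairs share one degrees-of-freedom value, the
minimum p per permutation equals the p of the maximum |correlation|, which
is what the code computes. A Beta(a, b) distribution is fitted to the 1000
minima and the gene-level p is its CDF at the observed minimum — this
extrapolates below the 1/(n_perm+1) empirical resolution. Two permutation
modes exist: the default permutes covariate-residualized expression (fast;
covariates are not re-fitted inside permutations), and an exact mode
re-residualizes every permuted matrix. On the synthetic cohorts the two
agree to well within the beta-fit noise.

**Beta fit.** Method-of-moments start, Newton refinement on the
log-likelihood (digamma/trigamma system), 100 iterations, damped steps to
stay in the positive orthant; on a singular Hessian, non-convergence or a
degenerate sample the moments estimate is returned and flagged. Minima are
clipped to (1e-300, 1 − 1e-16) before taking logs.

**FDR.** Storey q-values with π₀ from the λ-grid smoother (λ = 0.05…0.95
step 0.05, cubic smoothing spline evaluated at λ = 0.95, clipped to
[0, 1]; π₀ is floored at 1/m inside the q-value transform). Below 100
p-values the estimate is unstable, so π₀ = 1 (plain BH) is used and
logged. Ties in the per-gene best pair are broken by smaller |TSS
distance|, then lexicographic variant id; TSS distance is signed by
strand.

## Stepwise conditional analysis

One global gene-level threshold — the maximum beta-adjusted p among eGenes
at 1% FDR — is shared across genes (the alternative, per-gene thresholds,
is not implemented because the catalog-level threshold is what makes
signal counts comparable across genes). Conditioning adds discovered
signal dosages as covariates. The forward stage is capped at 10 iterations
per gene to bound runtime; in all simulations the cap never binds.
The backward stage tests signals in forward-discovery order and — the one
subtle choice — conditions each test on the signals *currently in the
model*, not the original forward list: once a signal is dropped it is no
longer controlled for. With the original-list variant, two near-proxies of
one causal variant eliminate each other (each explains the signal when the
other is conditioned on), leaving zero signals; sequential conditioning
keeps exactly one, which is the behavior a proxy pair should have.
Per-(gene, iteration) permutation seeds derive deterministically from the
master seed.

## Sharing (π₁) and replication

π₁ = 1 − π₀ over the replication tissue's nominal p-values at the
discovery-significant (feature, variant) pairs, with the same Storey
smoother. Estimates are clipped to [0, 1]; below 50 pairs a
wide-uncertainty warning is emitted. Fixed-pair replication re-runs the
q-value machinery within the restricted pair set only. Nominal (not
beta-adjusted) replication p-values are used: the pair set is fixed, so no
per-gene multiplicity remains to absorb.

## Deconvolution and interaction eQTLs

The signature matrix takes, per reference population, the genes most
*upregulated* versus the mixed tissue (two-sample t on log₂(x+1), signed,
top 500 by default), unions them across contrasts, and stores log₂ median
expression in each pure population. Ranking by |t| instead would let each
contrast pick other populations' markers (down-regulated genes score
highly too) and leave planted markers uncovered.

Fractions solve min‖S f − x‖² subject to f ≥ 0, Σf = 1: non-negative least
squares on the sum-augmented system (constraint weight 1e6 × max|S|),
then an equality-constrained KKT polish on the active support, which makes
noiseless convex combinations exact to < 1e-6. A rank-deficient signature
raises with the collinear cell-type pairs named. Deconvolution is meant to
run on pre-PC-adjustment expression — the PCs would absorb exactly the
composition signal being estimated.

Interaction scans fit y ~ 1 + d + f + d·f per known eQTL and t-test the
product term (n − 4 df). The permutation null permutes the cell-fraction
vector across samples — keeping the genotype–expression pairing, hence the
marginal eQTL, intact — jointly for all tests per replicate; the empirical
FDR at threshold t is (mean null discoveries at t)/(observed discoveries
at t), monotonized. Permuting genotypes instead is a configurable
alternative the permutation target leaves open, but it would break the
marginal association the test is supposed to preserve. Planted interaction
coefficients in the generator and power checks are expressed per SD of the
cell fraction, the same convention as main-effect slopes (residual-SD
units); a coefficient of 1.0 per SD at n = 400 is detected essentially
always, whereas the same number read per unit fraction corresponds to a
~3σ effect and is not reliably detectable at 1% FDR.

## NES

The observed statistic is the median over leads of the per-variant maximum
|slope| across all tested exons (nominal-scan slopes regardless of
significance — thresholding to significant eQTLs would censor the null).
Matching bins, shared with the annotation enrichment: MAF deciles of the
universe, |TSS distance| in 5 equal log₁₀ bins, LD-partner count
(r² ≥ 0.99 within 1 Mb) quartiles, nearby-gene count in {0, 1, 2, 3+}.
Empty joint bins relax components in the order gene count → LD count →
distance → MAF. A lead's own row is excluded from its pool — a matched
control must be a different variant; with fine bins and a modest universe,
self-inclusion drags every null median toward the observed value and
deflates enrichment — unless nothing else matches after full relaxation,
in which case the lead stands in for itself (`exclude_self=False` restores
strict self-matching, under which NES = 1 exactly when the universe is the
lead set itself). Sampling is uniform within the pool, one independent
draw per lead per replicate, with replacement across 15,000 replicates.
NES is the median of observed/null ratios, the one-sided 95% bound the 5th
percentile, and p the fraction of ratios < 1, floored at 1/(n_replicates+1)
rather than reported as zero.

## Annotation enrichment

Coordinates are BED 0-based half-open; a SNP at 1-based position p is the
interval [p−1, p). Interval queries go through per-chromosome interval
trees; a brute-force all-pairs scan is the test oracle. A locus overlaps a
feature iff the lead or any r² > 0.99 proxy (in-sample LD, 1 Mb window)
intersects it; proxy sets are precomputed once per dosage matrix and
shared across feature tracks. Fold = unique input-locus overlaps / mean
control-set overlaps (~500 matched controls per locus). The enrichment p
is the Poisson-binomial upper tail over the per-locus control overlap
frequencies — exact dynamic-programming convolution up to 50 loci, normal
approximation with continuity correction beyond.

eSNP filtering for effect-size analyses: q < 0.01, MAF ≥ 0.2 (effect size
varies inversely with MAF, so a floor removes that confound), then greedy
best-first LD pruning at r² < 0.8 within 1 Mb. Stretch enhancers are
merged adjacent enhancer-class segments longer than 3 kb; typical
enhancers are unmerged segments under 800 bp. Context contrasts use
two-sided Wilcoxon rank-sum on |slope|, skipping contexts with < 5 loci.
The effect-size-binned footprint analysis median-splits the filtered
eSNPs by |slope|, prefilters motifs by matched-control enrichment over the
bulk set at Benjamini–Yekutieli FDR < 1%, then reports each surviving
motif's fold in the high and low bins separately.

## Motif directionality

Information content per PWM position is 2 + Σ p log₂ p bits (uniform
background, 0·log 0 = 0). An eSNP–footprint instance is eligible iff the
overlapped position has IC ≥ 0.7, the position's most probable base is
unique (ties make the instance ineligible), and that base equals the
effect or non-effect allele; minus-strand occurrences map the position and
complement the alleles. The slope is re-keyed to the preferred base
(negated when the preferred base is the non-effect allele); zero slopes
are excluded and logged. The directionality fraction over ≥ 10 instances
is tested against 0.5 by exact two-sided binomial with BH FDR at 10%
(BY is reserved for the footprint-enrichment prefilter, where the
correlated motif family structure warrants it).

## The synthetic-data generator

One chromosome; each gene owns a 2 Mb window (cis windows laid back to
back), TSS at the window center, 50 variants per window by default.
Haplotypes follow a first-order copying chain within LD blocks: each
allele is copied from the previous variant with probability `ld_decay`
(default 0.9) and drawn fresh at that variant's frequency otherwise, so r²
decays geometrically with index distance; blocks (default 10 variants) are
independent. The chain-implied expected frequency is stored per variant
(`sampled_maf`) and is what the realized MAF fluctuates around. Expression
is baseline + planted slope × dosage on the affected exon subset + a
per-gene laboratory offset (four labs, emulating multi-center processing)
+ a cell-fraction-weighted per-gene signature (Dirichlet fractions over
three cell classes) + Gaussian noise, clipped at zero as a stand-in for
scaled counts — quantile normalization downstream makes the marginal scale
irrelevant. Planted |slopes| are drawn in residual-SD units (default mean
0.8, SD 0.2); secondary signals require in-sample r² < 0.05 with the
primary. Chromatin states are seeded on the causal variants (alternating
stretch-class > 3 kb and typical < 800 bp enhancer segments, merged when
they collide) with background promoter/enhancer/repressed/quiescent
segments filling the gaps; ATAC peaks nest inside open states and footprint
occurrences nest inside peaks. Footprint PWMs (length 12, informative
positions ≈ 1.25 bits cycling through all four bases) are placed so the
preferred base at the SNP realizes the motif's planted class — activating,
repressive, or neutral — with a 10% flip probability by default. GWAS lead
lists mix causal variants (largest planted effects first) with random
background variants at a tunable fraction.

All randomness derives from one master seed through fixed per-component
sub-streams, so identical configs reproduce byte-identical outputs.

What the generator does **not** emulate: read-level sampling noise and
count overdispersion, population structure and relatedness, indels and
sex chromosomes, reference-panel LD that differs from in-sample LD,
realistic gene density (windows never share variants), and correlated
exon usage beyond shared gene effects. Passing tests therefore demonstrate
the statistical machinery is correct and calibrated under the assumed
generative structure, not that real-data preprocessing issues (mapping
bias, batch-by-genotype confounding, panel mismatch) are handled.

## Problem sizes and tolerances in the test suite

The acceptance-style tests run: 300 null genes (n = 200, 50 variants, 3
exons, 1000 permutations) for calibration; 200 mixed genes for
beta-vs-empirical fidelity (Spearman ρ > 0.99, mean |log₁₀ ratio| < 0.15
on p ∈ [0.01, 1]); 100 two-signal genes (|slope| = 0.8 SD, causal
r² < 0.05, n = 300) for stepwise recovery (≥ 80% exact-2, ≤ 5% false
secondaries); 2000 pairs per sharing level for π₁ (± 0.07); 100 mixtures
for deconvolution (MAE < 0.05 at 10% noise, < 1e-6 noiseless); 2000 null
and 50 planted replicates for interactions; 50 null runs and one
15,000-replicate power run for NES; ≤ 10⁴-interval brute-force oracles for
overlap enrichment; and ~200 instances per motif class for directionality.
The whole suite runs in about two minutes on one CPU; `scripts/acceptance.py`
in about half a minute.

## Known limitations

- LD is computed in-sample from study dosages; the reference-panel pruning
  a consortium pipeline would use is supported only by swapping in a panel
  through the same dosage container.
- The mixed-model residualization used upstream of interaction tests in
  consortium pipelines (random terms for sequencing batch) is approximated
  by fixed-effects residualization; variance components are not estimated.
- Permutation counts are fixed (no adaptive stopping), and the beta fit
  assumes the minima are well inside (0, 1) — genes with a single testable
  variant at tiny n can produce degenerate fits, which fall back to
  moments and are flagged.
- The expression-PC count is a configuration knob (default 25); the
  within-laboratory permutation experiment for choosing it is out of
  scope.
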