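# Methods

This note documents the models, defaults and numerical choices behind
`her2mtgx`, and what the synthetic-cohort validation does and does not
establish.

## Expression normalization

TPM is computed per sample as `1e6 · (count/length_kb) / Σ (count/length_kb)`;
columns sum to 1e6 by construction and an all-zero sample is an error
rather than a silent NaN column. All gene-level modelling runs on
log2(TPM+1): on that scale ANOVA coefficients are log-fold-like, which is
what makes a fixed clipping window of ±3 meaningful.

For clustering, each sample's log2(count+1) vector is centered and scaled
(population SD), then winsorized. The winsorizing smoother is piecewise
linear — identity on [τ_low, τ_high], constant outside — with defaults
τ_low = −2, τ_high = +2 on the z scale. The published per-sample
transformation this emulates uses a proprietary smoother whose exact form
is specified elsewhere; the piecewise-linear version keeps the two
properties the pipeline relies on (monotonicity and idempotence) while
remaining self-contained, and the caps are exposed in configuration. Gene
filtering keeps genes whose across-sample MAD of the transformed values
exceeds 0.2; this is a spread filter, so a gene that is constant across
samples is always removed and `min_spread = 0` keeps everything.

## Cluster-count selection

Samples are clustered by Ward linkage on Euclidean distances. For each
candidate k the Calinski–Harabasz index CH(k) = [B/(k−1)]/[W/(n−k)] is
computed on the dendrogram cut; candidates are the local maxima of the CH
curve (endpoints included when maximal), and among candidates the cut with
the largest Dunn index (minimum inter-cluster distance over maximum
cluster diameter) wins. Ties break toward smaller k, for parsimony. The
Dunn index is undefined when every cluster is a singleton or duplicate set
(zero maximum diameter); such cuts are excluded from arbitration.

The post hoc Dunn rank test used for the amplicon comparison is the
standard pairwise z on pooled mid-ranks with tie correction,
Bonferroni-adjusted over the pairs; the package pairs it with the ordinary
one-way ANOVA F for the omnibus test. The 17q12 core-amplicon fixture
carries ERBB2 plus thirteen co-amplified neighbours (CDK12, NEUROD2,
PPP1R1B, STARD3, TCAP, PNMT, PGAP3, MIR4728, MIEN1, GRB7, IKZF3, ZPBP2,
GSDMB) and is overridable; the list reproduces its source's printed gene
symbols verbatim, even though that source's own count of the region
("nine genes besides ERBB2") disagrees with the thirteen symbols it
prints.

## Exclusive-module signature

Per gene, one-way ANOVA across the three molecular groups on log2(TPM+1).
Coefficients are group-mean deviations from the unweighted mean of the
three group means, so they sum to zero regardless of group sizes; R² is
SS_between/SS_total with the ordinary (size-weighted) grand mean, and p
comes from the F test. FDR adjustment is Benjamini–Hochberg. The clip is
g(β) = 3·tanh(β/3): odd, strictly monotone, slope 1 at the origin,
asymptotes ±3, so g crosses the selection threshold 2.7 at
β = 3·atanh(0.9) ≈ 4.42.

Selection: gene joins module k iff q < 0.01, R² > 0.3, g(β_k) > 2.7 and
g(β_j) ≤ 0 for both other groups; its weight is g(β_k). The rule is
monotone in the weight threshold (raising it can only remove genes), and
the exclusivity clause is what makes the modules disjoint by construction.

Scoring standardizes each module gene across the scored cohort before
taking the weighted mean (normalized by Σ weights so modules of different
sizes are comparable). Cohort-wise standardization was a genuinely open
choice — fixed reference parameters would also be defensible — and was
chosen because it is what makes the score independent of platform scale
and location, which the cross-platform tests exercise. Profile = argmax
score, ties resolved HER2 > Basal > Luminal (clinically, a HER2 call is
the actionable one). A published 31-gene membership list ships as a
fixture with unit weights, because the trained weights are confidential;
with unit weights each score is a plain mean of standardized expression.

## Responder triage and comparison

The Wald band uses the one-tailed normal quantile z_α = Φ⁻¹(1−α)
(≈ 2.326 at α = 0.01), which reproduces the printed 37%/49% band at
p̂ = 43.2%, n = 396; the two-tailed 2.576 does not (its upper bound rounds
to 50%). Predicted probabilities strictly above/below the band are
good/bad; boundary equality is regular, so shrinking the band can only
move samples out of the regular class. PPV/NPV are observed outcome rates
within the triage classes and are reported as missing when a class is
empty. Predicted probabilities are in-sample, matching the analysis the
triage quantities summarize; users wanting out-of-sample calibration can
refit on held-out strata. Classifier-vs-classifier contrasts use the exact
McNemar binomial on discordant pairs, restricted to true responders for a
sensitivity comparison.

Association tests: Pearson chi-squared without continuity correction when
all expected counts are ≥ 5 (the uncorrected form reproduces the printed
ER×HER2 p = 0.042; Yates gives 0.056), Fisher's exact for small 2×2
tables, and a fixed-margins Monte-Carlo permutation of the chi-squared
statistic for larger sparse tables (seeded, add-one p estimate).

## Bayesian lift

Conjugate Beta posteriors with a uniform Beta(1,1) prior. The lift
functional is P(θ_B > (1+δ)·θ_A): δ = 1.0 asks for a doubling, δ = −0.2
expresses a 20% reduction. Monte Carlo uses 10⁵ draws per arm from a
seeded generator; an independent quadrature oracle integrates
f_A(a)·S_B((1+δ)a) over [0,1] and the two agree within 0.005 at 10⁵ draws
(standard error of a proportion at that size is ≤ 0.0016). The printed
class-level confidences from the neoadjuvant analysis are not reproducible
from the printed marginal counts alone (the exact inputs and lift
functional are ambiguous), so the module is validated by oracle
equivalence rather than against those numbers.

## Survival

Follow-up is administratively censored at 240 months (idempotent).
Kaplan–Meier medians are the first time the product-limit estimate drops
to ≤ 0.5 (NaN when never reached). Cox fits use lifelines with the Efron
tie approximation; covariates pass a univariate screen at p < 0.1 before
the multivariate fit. Categorical covariates are one-hot encoded against
their first level.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes:

- **Counts**: negative binomial via gamma–Poisson mixing, dispersion 0.2
  (field-typical for bulk RNA-seq), baseline means log-normal
  (log2 mean 5, SD 2). Each planted module's genes are up-shifted by the
  configured log2 effect in their own group only.
- **Effect size**: default 8 log2 units per module. Under sum-to-zero
  three-group coding this yields ANOVA deviations of (2/3)·8 ≈ 5.33,
  comfortably past the 4.42 crossing that the clipped-weight threshold
  demands, so the planted modules are recoverable by the documented
  selection rule; amplicon-driven markers such as ERBB2 in truly amplified
  versus basal tumors show differences of this order on the TPM scale.
- **Copy number**: gene-level log2 ratios N(0, 0.15), with the 17q12 core
  genes shifted +1.0 in the HER2 group.
- **IHC/ISH**: ERBB2 dosage 2^(log2 ratio) maps to 3+ (≥1.8), 2+
  ([1.2, 1.8)), 1+/0 below, with a 5% random miscall rate; the ISH ratio
  and copies are the dosage with multiplicative log-normal noise.
- **pCR**: Bernoulli from a logistic model on the true (noise-free,
  standardized) module scores — intercept −0.3, β_HER2 = 0.8,
  β_Luminal = −0.3, β_Basal = 0 — plus per-stratum offsets (0, +0.2, −0.2)
  over three study strata with membership probabilities (0.5, 0.3, 0.2).
  Note the three indicator-derived true scores sum to a constant, so
  recovery fits use the HER2+Luminal design.
- **Survival**: exponential times with hazard
  0.008·exp(0.6·z_HER2 + stage effect) per month (stage log-HRs 0.7/1.4
  for stages 2/3), independent exponential censoring targeting ~30%.
- **Microarray view**: counts-per-million through a monotone log-scale
  affine map (0.9·log2(CPM+1)+2) plus Gaussian noise — array intensities
  track per-sample concentration, which is why the view is built on CPM
  rather than raw counts.

Default cohort: 60 samples per group, 2000 genes, 20 genes per module.
These sizes keep the full pipeline under a few seconds while leaving all
recovery margins wide.

What the generator does **not** emulate: realistic gene–gene correlation
beyond the planted modules, batch effects beyond per-stratum intercepts,
platform-specific probe effects, or informative censoring. Passing tests
therefore demonstrate the correctness of the estimators and selection
rules under the assumed generative model, not robustness to the
correlation structure and artifacts of real cohorts.

## Problem sizes and determinism

The test suite and acceptance script size their simulations to finish in
seconds while keeping every pass/fail margin wide: 20 cohorts for
signature recovery, 100 seeds for cluster-count and logistic recovery in
the test suite (25 in the script), 10–20 posterior pairs for the
Monte-Carlo/quadrature comparison, 500 subjects for Cox recovery. All
randomness flows from explicit seeds; property tests run derandomized.

## Known limitations

- The winsorizing smoother and the gene-filter threshold are pragmatic
  stand-ins for a published transformation whose exact parameters are not
  public; results on real cohorts will differ in detail.
- The published signature fixture carries unit weights, so its scores are
  unweighted means; it reproduces printed module memberships verbatim,
  including one gene (FOXA1) whose printed module assignment conflicts
  with its canonical biology.
- Simulated-p Fisher for r×c tables uses a permutation of one margin, not
  the network algorithm; p-values carry Monte-Carlo error of order
  1/√n_mc.
- The responder triage assumes the logistic model's in-sample
  probabilities are calibrated; no shrinkage or cross-validation is
  applied by default.
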