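# Methods

This note documents the statistical procedures the package implements, the
choices made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the numerical conventions. No
empirical claim is made here that the test suite or `scripts/acceptance.py`
does not itself compute.

## Study design being modeled

A cross-sectional comparison of the amniotic-fluid proteome between two
gestational-age groups: midtrimester (16–24 weeks, n = 15) and term not in
labor (37–42 weeks, n = 13), with ~1310 proteins quantified in relative
fluorescence units (RFU) by an aptamer panel run in three serial dilutions
across plates. Analyses operate on the log2 scale after standardization.
Samples in rows is the package-wide orientation; readers transpose on a
declared orientation flag, so analyses are orientation-invariant.

## Normalization

The vendor's three-step standardization is described only qualitatively in
assay documentation, so the package implements a transparent median-ratio
emulation, each step optional and audited by a factor table:

1. **Hybridization** (per sample): factor = median over control analytes of
   reference/observed; afterwards each sample's median control ratio is 1.
2. **Median** (per sample × dilution bin, with a global fallback flag):
   factor = median over the bin's analytes of (analyte's across-sample
   median / analyte's value in the sample). Whether the original analysis
   normalized within bins or globally is not documented; within-bin is the
   default since dilution bins are handled separately by the assay.
3. **Plate calibration** (per plate × analyte): factor = reference /
   calibrator level, the calibrator level being the plate's calibrator-well
   reading when available and otherwise the median over the plate's own
   samples (a defined degenerate-input behavior).

Factors always multiply observed values toward the reference
(factor = reference/observed), fixing a direction ambiguity. Hybridization
and plate factors are pure scale corrections and invert exactly on
generator data; the median step is data-dependent (its factors involve
medians of noisy values), so it preserves group contrasts only up to small
distortions (a few hundredths of a log2 unit on study-sized cohorts —
printed by `examples/02`), which is why the exact chain-inversion property
is stated and tested for the hybridization + plate subchain.

## Cohort statistics

Categorical variables: two-sided Fisher's exact test with the
point-probability rule (sum of hypergeometric probabilities of all tables
with the observed margins no more probable than the observed table). This
convention reproduces all six published contingency-table p-values at three
decimals and is checked against exact rational enumeration in the tests.
Continuous variables: Welch's unequal-variance t-test with
Welch–Satterthwaite degrees of freedom; summaries are median (IQR) or
count/denominator (%), with per-variable missing-value counts (the
published table footnotes one missing BMI value without stating its group,
so missingness is never attributed to a group).

## Differential abundance

Per-analyte OLS on intercept + group indicator + covariates. Fetal sex and
maternal age are the default covariates because those were the imbalanced
demographics; maternal age enters as a continuous covariate (whether the
original analysis categorized it is unstated). The group coefficient is the
log2 fold change (term − midtrimester, or late − early midtrimester for the
within-midtrimester contrast split at 21.05 weeks, which realizes the
disjoint printed ranges 16.4–21.0 / 21.1–24.0 — gestational ages recorded
at one decimal cannot tie).

Variance moderation follows the empirical-Bayes moderated t of Smyth
(2004): the prior (d₀, s₀²) is fitted by method of moments on log s² using
digamma/trigamma identities, with the trigamma inverse solved by Newton
iteration; non-positive excess variance yields d₀ = ∞. The posterior
variance is (d₀s₀² + d·s²)/(d₀ + d) and the moderated t has d₀ + d degrees
of freedom. Two limits anchor correctness: d₀ = 0 reduces to per-analyte
OLS t-tests (asserted to 1e−10), and d₀ = ∞ pins every variance at s₀².
The implementation also matches Bioconductor limma's `eBayes` on shared toy
data to ~1e−15 (test via Rscript). At least 10 analytes with positive
residual variance are required to fit the prior; below that the caller must
supply d₀.

Calls: q < 0.1 strict (Benjamini–Hochberg over all analytes) **and** fold
change ≥ 1.5 inclusive; fold change is reported unsigned with a separate
direction column, matching the published table layout. The BMI sensitivity
analysis refits with BMI added and reports the Pearson correlation of fold
changes over the reference call set plus the direction-agreement fraction.

## PCA

Columns are centered and unit-scaled before SVD (analytes span orders of
magnitude in RFU; scaling is exposed as a flag and recorded, since the
published figure's settings are unstated). Component signs follow a
deterministic convention (largest-magnitude loading positive), and the
PC1–gestational-age correlation is reported both signed and as |r| because
a component's sign is arbitrary. Zero-variance analytes are dropped and
recorded when scaling.

## Network modules

Biweight midcorrelation with tuning constant 9 (weights (1−u²)² for
|u| < 1, u = deviation/(9·MAD)); columns with zero MAD fall back to Pearson
with a logged warning. Signed adjacency ((1+ρ)/2)^β with β = 22 as in the
original analysis; topological overlap in the standard form; average
linkage on 1 − TOM.

The upstream analysis used a package's defaults for everything except
networkType/corType/power; those defaults are not recoverable from the
text, so this package defines its own transparent stand-ins, all
configurable: static tree cut at height 0.995, minimum module size 20,
module merge at eigenprofile correlation 0.85. The static cut + size filter
+ eigenprofile merging replaces the hybrid dynamic tree cut; adequacy is
defined by recovery tests (mean adjusted Rand ≥ 0.8 against planted
three-module truth at n = 28 samples). A percentile-based cut
(`cut_height="auto"`, the 99th percentile of merge heights) is available
but is not the default: on pure-noise data nearly all merge heights
concentrate just below the maximum, so a percentile cut collapses
everything into one spurious cluster, whereas the fixed cut leaves noise
unclustered (label 0, the background/noise module).

Module eigenprofiles are the unit-norm first principal component of the
standardized member profiles, oriented so the mean member correlation is
nonnegative; kME is the Pearson correlation of an analyte's profile with an
eigenprofile; hubs are the top-4 members by kME (ties broken by analyte
id). Gestational-age profiles use LOESS implemented as local quadratic
regression with tricube weights on the ⌈span·n⌉ nearest points (span 0.75
default), evaluated on an even grid over the data range. The pipeline's
module input set is the union of analytes significant in either contrast,
mirroring the published analysis.

## Enrichment

Non-conditional upper-tail hypergeometric tests of flat GMT gene sets
against the panel's gene universe; term relationships (ontology structure)
are not modeled. "Hits" are query genes inside the term. Terms with fewer
than three hits are excluded before BH adjustment; q < 0.05 flags
enrichment. BH is applied within each supplied collection, since published
counts were reported per ontology branch. Multi-gene analytes (e.g. an
aptamer recognizing a heterodimer) contribute every mapped symbol once.

## Tissue signatures

"30 times higher than all other tissues" is operationalized as ≥ 30× the
**median** over the other tissues (the comparator is a flag; median matches
the atlas convention the wording points to). Signatures intersect the panel
and cap at the top 20 genes by ratio, ties broken deterministically by gene
id. Scoring: per analyte Z = (value − reference mean)/reference SD with the
midtrimester group as reference, averaged per sample over the signature;
zero-reference-SD analytes are dropped with a warning. Scores are exactly
invariant to any analyte-wise affine rescaling of the input. Group
comparison: Wilcoxon rank-sum, exact null when both groups have ≤ 25
observations and no ties, normal approximation with tie correction
otherwise; BH across tissues at q < 0.05; direction is the sign of the
median difference (term − midtrimester).

## Cross-omics concordance

Matching is by upper-cased gene symbol; a multi-gene analyte matches if any
symbol matches, and an analyte matching several prior rows keeps all pairs
with a multiplicity flag (analyte-level rather than gene-collapsed pairs;
both modes of thinking are supported by filtering the pair table). The
Spearman ρ with tie-corrected p and the same-direction fraction are
computed over pairs significant in both studies (≥ 3 required); a zero fold
change counts as a direction disagreement, a conservative rule for a case
the data never produces. The three published comparisons require external
tables that are not reprinted, so they are exercised on constructed prior
tables with a controlled target correlation.

## The synthetic-data generator

The generator emulates the study conditions: 15 + 13 samples with
gestational ages uniform on 16.4–24.0 and 37.0–41.0 weeks (matching the
printed ranges while keeping both sides of the early/late split populated),
1310 assay analytes plus 12 noise-free hybridization controls, dilution
bins, two plates, per-sample log-normal hybridization factors (ln-sd 0.1)
and per-plate × analyte calibration factors (ln-sd 0.05), and calibrator
wells carrying the plate-scaled reference profile so plate factors are
exactly estimable — the analogue of real calibrator wells.

Biology on the log2 scale: per-analyte baselines N(10, 1.5²); noise
variances s² ~ s₀²·d₀/χ²(d₀) with (d₀, s₀²) = (4, 0.09), i.e. typical
within-group SDs around 0.3–0.4 log2 units with an inverse-chi-square tail,
a realistic spread for log2 RFU; 25% of analytes carry a true group effect
|log2FC| = log2(1.5) + Exponential(0.7) with random sign, guaranteeing
planted effects exceed the fold-change calling floor so recovery is
well-posed; three correlated modules sized 131/121/154 (the published
module sizes, scaled proportionally for smaller panels) built from latent
factors with sign-coherent loadings Uniform(0.4, 0.9); six tissue
signatures of 10 genes, two of which are shifted ±1 reference-SD at term;
small fetal-sex and maternal-age effects on 10% of analytes (BMI effects
default to zero and are planted only for the sensitivity test).

Design choices that keep the truth unambiguous: the differential, module,
and tissue analyte sets are **disjoint**, so each recovery test scores
exactly the mechanism it targets; module factors are gestational-age-
independent by default (`module_ga_weight=0`), so `is_de` is the complete
truth for false-discovery accounting — GA-linked factors (used in the PCA
demonstration via `module_ga_weight≈0.9`) would create real group effects
outside `true_log2fc`. Tissue shifts are real group effects but are
recorded separately (`group_effect_total`) and sized well below the
fold-change floor, so they contribute at most a handful of boundary calls.
The generator plants a **step** group effect, not a continuous gestational-
age trend; consequently the late-vs-early midtrimester contrast on default
synthetic data finds essentially nothing — the within-midtrimester
machinery is exercised by the contrast interface and boundary tests, not by
planted signal.

What passing tests therefore do and do not show: they demonstrate that the
implementation recovers planted effects, factors, modules, signatures, and
concordance under idealized conditions — complete data, Gaussian noise,
exact controls/calibrators, effects disjoint by mechanism. They do not
certify behavior under real-data features the generator omits: missing or
censored values near detection limits, aptamer cross-reactivity, batch ×
biology confounding, heavy-tailed or skewed residuals, within-trimester
trends, or correlated truth mechanisms.

## Numerical conventions and limitations

Problem sizes used by the test suite and acceptance script (chosen as
study-sized or scaled-down replicates): 100 replicate cohorts for
false-discovery and sensitivity averages, 20 × 2000 analytes for
hyperparameter recovery, 20 networks of ~500 analytes for module recovery,
50 prior tables for concordance. BH q-values are capped at 1 and monotone
in p by construction. The trigamma-inverse Newton iteration runs to
relative tolerance 1e−10. Matrix inversion in the OLS fits uses the shared
(X'X)⁻¹ since the design is common to all analytes; rank deficiency raises
rather than silently dropping coefficients. Ingest rejects missing values
(the assay matrix is complete); an opt-in flag drops incomplete analytes
for foreign data. Known limitations: no moderated F-tests or >2-group
contrasts, no ontology-aware (conditional) enrichment, no dynamic tree cut,
no limit-of-detection handling, and the normalization is an emulation of
the vendor chain's intent, not a bit-exact reproduction.
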