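# Methods

## Scope and data model

`gutlink` analyses two linked data sets per cohort: per-gut-location
taxa tables (samples × ASVs or genera; counts or relative abundances)
and one serum metabolite feature matrix (samples × LC-MS features;
non-negative intensities with 0 meaning missing, per-sample injection
order and pooled-QC flags, per-feature MSI annotation level). Sample
metadata carries sex, slaughter batch and the fatness phenotype. The
package starts from feature tables; raw read processing (denoising,
taxonomy assignment) and raw spectra processing (peak picking,
annotation) are upstream of its scope.

## Preprocessing

**Taxa.** Count tables are rarefied to a common depth (default 19,000
reads, the conventional floor for this assay) by seeded subsampling
without replacement (multivariate hypergeometric draws), so every row
sums to the depth exactly. Taxa are retained when their mean relative
abundance exceeds 0.05% *and* they are detected in more than 5% of
samples. The abundance rule is interpreted as a mean across samples
(the common practice where the wording is ambiguous between mean, max
and per-sample); both thresholds and the strictness of the prevalence
inequality are configurable. Filtering preserves the original column
values; row sums below one after filtering are intentional.

**Alpha/beta diversity.** Observed features and Shannon index (base 2
by default, configurable) summarize within-sample diversity; Bray-Curtis
dissimilarity feeds a classical principal-coordinates analysis
(double-centered squared distances, eigendecomposition; negative
eigenvalues are reported but contribute no axes, and explained fractions
are taken over the positive spectrum). Group separation is tested by
ANOSIM with average ranks on ties and a permutation p-value using the
(1 + hits)/(1 + permutations) correction; for small cohorts an exact
mode enumerates every distinct label assignment. "PCA on Bray-Curtis"
is implemented as PCoA, the mathematically coherent reading; a plain
covariance PCA of abundances remains available through scikit-learn for
users who want the literal variant.

**Metabolites.** The QC chain is: (1) drop features missing in >80% of
biological samples or >50% of QC injections, then keep features present
in >50% of biological samples (the two presence rules are applied
sequentially; their order is not material for the defaults since the
second implies the first's biological clause); (2) drift correction:
per feature, a LOWESS curve is fit to log QC intensity over injection
order and every intensity is divided by f(order)/median(QC), with
constant extrapolation past the terminal QCs — if the fitted correction
would raise a feature's QC RSD the feature falls back to a constant
factor, so drift correction can never degrade QC repeatability, and
zeros stay zero; (3) features whose QC RSD (sd/mean over nonzero QC
values) exceeds 30% are removed — strictly more than, so a feature at
exactly 30% survives — and features with fewer than two nonzero QC
values are removed as unassessable; (4) association analyses use the
MSI level 1/2 annotated subset when one exists. RSD is computed after
drift correction; the smoother is a contract detail — the guarantee is
the RSD non-increase, not the fitter. Before modelling, each feature is
min-imputed (half-minimum behind a flag), log10-transformed and
z-standardized, which also makes the scan invariant to any global
rescaling of raw intensities.

## The two-part association engine

For each (taxon, metabolite) pair within one location and taxonomic
level, the metabolite is residualized by OLS on an intercept plus
dummy-coded sex and slaughter batch (aliased columns dropped). Two
sub-tests follow:

* binary: OLS slope of the residual on the presence indicator;
* quantitative: OLS slope of the residual on standardized log10
  relative abundance, restricted to present samples (≥10 required,
  configurable).

Each slope t statistic is mapped to a Z score through the exact t
distribution, z = sign(t)·Φ⁻¹(1 − p_t/2). At the cohort sizes this
package targets (hundreds of samples) this is numerically identical to
using t directly, but it keeps the null calibration of the combined
statistic exact when the quantitative part runs on few samples. Under
the null the two parts are orthogonal projections of the same response
(the centered presence vector restricted to the present set is constant,
while the within-set standardized abundance is centered), so the
unweighted combination z_meta = (z_b + z_q)/√2 is again standard normal
and its two-sided normal p-value is exact. Parts policy: prevalence ≥
0.95 runs the quantitative part only (presence nearly constant); fewer
than 10 present samples runs the binary part only; fewer than 3 samples
in either presence class skips the binary part. The positive direction
means higher metabolite with presence/abundance.

BH adjustment is applied across all pairs of one (location, level) scan
— the family within which significant-pair counts are reported.
Significant pairs (q < 0.05) are re-tested by partial Spearman
correlation: both variables rank-transformed (average ranks), numeric
covariates rank-transformed as well, ranks residualized on the covariate
design, Pearson correlation of the residuals with a t p-value on
n − 2 − k degrees of freedom (the R `pcor`/pingouin convention). The
replication fraction is the share of two-part hits that stay significant
after BH within the replicated family.

## Variance explained

The proportion of a metabolite's variance attributable to one location's
microbiota is estimated by repeated cross-validation rather than
in-sample fit, because in-sample R² with data-driven taxon selection is
badly optimistic at realistic effect sizes. Per round: a random 90/10
train/test split; taxa with two-part p < 0.05 on the training samples
are selected; the covariate-residualized metabolite is regressed
(minimum-norm least squares) on an intercept plus, per selected taxon,
its presence indicator and zero-filled standardized log abundance;
out-of-sample R² = 1 − SSE/SST is scored on the held-out samples with
the training mean as baseline. The estimate is the median over rounds
(100 by default), clamped to [0, 1]; rounds selecting no taxa contribute
zero. An optional permutation p-value reruns the procedure on
label-permuted responses at a reduced round count. The out-of-sample
definition carries a known conservative bias: noise taxa that clear the
training threshold contribute pure prediction error, costing roughly
m·α·E[z²|selected]/n of R² (≈0.03 with 50 taxa at n=500), so a signal
constructed to explain 10% of variance is typically estimated near
6–8%. Estimates are labelled out-of-sample for that reason.

## Cross-location comparison

A pair is *shared* between locations when it passes the FDR threshold in
every member location independently — no cross-location meta-analysis —
matching how intersection counts are reported in this literature. Sign
concordance is recorded per shared pair (associations can genuinely flip
sign between gut segments). Genus- and ASV-level results are never
intersected with each other. Venn region counts are exact
inclusion–exclusion counts over the per-location significant sets; both
the feature-level and annotated-only orderings of the intersection are
available to the caller by filtering the input tables.

## Biomarker panel

The fatness workflow compares two extreme-phenotype groups (default 15
vs 15). PLS-DA (two components by default, reduced to the feasible rank
with a warning) on column-standardized log intensities yields VIP scores
normalized so that the mean squared VIP is exactly 1. Differential
metabolites satisfy VIP > 1 *and* two-sided Wilcoxon rank-sum p < 0.05
(Welch's t behind a flag; the rank test is the robust default at 15 per
group), reported with raw-scale group means ± sd. The panel is built by
bidirectional stepwise logistic regression minimizing AIC from the empty
model over the differential candidates; perfect separation at any step
falls back to a lightly ridge-penalized fit whose log-likelihood is
evaluated at the penalized coefficients, and a fallback in the final
model is flagged. AIC admits a noise variable with probability
P(χ²₁ > 2) ≈ 0.16 per candidate, so null panels are small but not always
empty; conversely, once two strong markers nearly separate 30 samples
the likelihood saturates and AIC legitimately declines further markers —
panel size is a parsimony judgement, not a recall guarantee. AUC is the
Mann-Whitney statistic with ties counted one half; single-marker AUCs
are oriented to [0.5, 1]. Alongside the in-sample panel AUC a
leave-one-out AUC (coefficients refit without the held-out sample, fixed
membership) is reported to expose selection optimism.

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes,
not the biology it abstracts. Per location, taxon prevalences are drawn
uniformly from a location-specific range (ileum 0.10–0.60; cecum and
faeces 0.20–0.90 — the small intestine carries sparser communities),
per-taxon log-mean abundances from N(0, 2), presence from Bernoulli
draws and abundance-given-presence from a log-normal with sd 1.0; rows
are renormalized to relative abundance (a sample losing all taxa gets
its most prevalent taxon restored first), optionally realized as
sequencing counts at depths drawn from 30,001–44,994 reads. Metabolite
log intensities are a per-feature baseline plus N(0, 0.3) sex and batch
shifts (5 batches), implanted effects, a log-linear injection-order
drift and N(0, 1) residual noise; pooled-QC injections (every 12
samples, as in standard run designs) replicate the feature baseline with
sd 0.05 analytical noise and the same drift; 2% of biological intensities
are set missing at random. Implanted effects act in the stated units of
the downstream test — a presence shift in residual-sd units and a slope
per sd of the taxon's *latent* log abundance. Implanting on the
renormalized community share instead would inject the total community
load into the metabolite and couple every other taxon to it through the
compositional constraint, leaving the implanted truth ill-defined; the
latent-abundance convention keeps truth pairwise while the scan still
tests renormalized abundances, so a small residual compositional leak
from dominant taxa remains and is visible as a slightly elevated
empirical FDR (≈0.06 at q < 0.05 in the acceptance simulations). The
fatness label ranks a logistic score on four designated metabolites
(plus standard-logistic noise) and median-splits it, giving exactly
balanced groups that mirror an extreme-phenotype design while keeping
the label stochastic.

What the generator does *not* emulate: taxon–taxon ecological
correlations beyond compositional closure, phylogenetic structure,
batch effects on taxa, non-linear or interaction effects, heavy-tailed
intensity noise, and structured (intensity-dependent) missingness.
Passing tests therefore demonstrate the statistical machinery is
correct and calibrated under the assumed generative model, not that the
model captures every feature of real cohorts.

## Problem sizes and numerical choices

The simulation-based checks run at deliberately moderate sizes chosen to
make their Monte-Carlo error small relative to the bands they assert:
null calibration pools 200 cohorts of 300 samples × 50 taxa × 20
metabolites (200,000 p-values, binomial se ≈ 0.0005 at α = 0.05); FDR
and power pool 50 cohorts with 20 implanted effects among 5,000 pairs;
variance-explained recovery averages five constructions at n = 500 in
which the causal taxon explains exactly 10% of the realized variance
(noise orthogonalized to the causal design, removing cohort-level
Monte-Carlo in the target); the biomarker recovery uses 200 replicates
of the 15 + 15 design. Permutation p-values use the +1 correction and
never return zero. Ties take average ranks everywhere. Degenerate
inputs (constant vectors, single-class labels, all-zero samples,
all-missing features) raise informative errors rather than propagating
NaNs; scan-level policy failures (a part that cannot run) are recorded
in `parts_run` instead of erroring. All randomness flows through
numpy Generators seeded from explicit arguments; per-stage substreams
are spawned from one SeedSequence so runs are byte-reproducible.

## Known limitations

* The two-part model tests marginal pairwise associations; compositional
  coupling between taxa is not modelled, and strongly dominant taxa can
  induce genuine (not spurious-by-error) associations for their
  neighbours.
* Stepwise AIC selection is greedy and, at 30 samples, liberal under the
  null and parsimonious under strong signal; the panel is a prediction
  device, not an inference on marker importance.
* The variance-explained estimator is conservative by construction (see
  above); comparisons across metabolites are meaningful, absolute values
  are lower bounds in expectation.
* Drift correction assumes the pooled QC tracks the biological samples'
  instrument response; it cannot correct sample-specific extraction
  effects.
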