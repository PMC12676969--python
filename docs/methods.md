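# Methods

This note documents the statistical procedures implemented in `endoprot`,
the defaults they ship with, and the design decisions taken where the
methodology left genuine freedom. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Data model and QC

NPX (Normalized Protein eXpression) is a relative, log2-scale abundance
unit; a difference of NPX values is therefore a log2 fold change. The
`NPXMatrix` container holds samples × proteins with per-sample AD/HC
labels and optional Olink subpanel tags.

**CoV filter.** The marker-variability filter computes CoV% =
100·sd/mean per protein. Because the CoV of log-scale values is not
scale-invariant, the default computes it on the linearised scale 2^NPX
(`scale="log"` switches to raw NPX). The default mode retains proteins
with CoV **above** the threshold (20%), i.e. a biological-variability
filter that discards flat, uninformative assays; because that convention
is unusual for assay QC, `mode="keep-below"` provides the conventional
noise filter. Proteins whose mean is zero on the chosen scale have an
undefined CoV and are dropped with a warning.

**Missing values.** Proteins missing in more than 25% of samples are
dropped; remaining gaps are median-imputed per protein, with counts
logged. **Scaling.** `zscale` centers and scales each protein to unit
variance (n−1 denominator); constant proteins map to zeros with a
warning.

## Endotype discovery

**k-means.** Lloyd's algorithm with k-means++ initialisation, best of 25
restarts by WCSS, run on z-scaled data (scaling prevents high-variance
proteins from dominating the Euclidean metric; a config flag disables
it). Cluster indices are canonicalised by descending size (ties broken by
the smallest member position) so labels are stable across runs. The
scree reports best-of-restarts WCSS for k = 1..10.

**Stability.** The cohort is perturbed by including/excluding the HC
samples: a k=2 patients-only model is compared with a k=3 all-samples
model. The HC-majority cluster of the all-data model is identified, the
patient-assignment contingency is matched by the Hungarian method, and
patients off the matched diagonal — in particular patients landing in the
HC-majority cluster — are reported as outliers.

**Reproducibility.** Per iteration: a random 70/30 split (the split
fraction is a package choice; it is configurable), independent k-means
(same k) on each part, a 500-tree random forest (sqrt-p features per
split) trained on the training part's cluster labels. Training accuracy
is resubstitution agreement; testing accuracy is agreement between the
forest's predictions and the testing part's own k-means labels,
maximised over cluster-label permutations (exact for k ≤ 4, Hungarian
beyond). Two independent k-means labelings carry no shared label space,
so some alignment convention is required; permutation matching is the
least committal. Medians over 100 iterations are reported in percent.
Degenerate iterations are skipped and logged; more than 10% skipped is a
hard error.

**Embedding.** Exact-gradient t-SNE (deterministic given the seed),
default perplexity min(30, (n−1)/3); per-cluster 95% ellipses are
chi-square(2) contours of a bivariate normal fitted to the embedded
coordinates.

## Differential expression

Per-protein OLS with intercept, a 0/1 contrast indicator, centered age
and 0/1 sex (centering does not change the contrast coefficient).
Because NPX is log2, the contrast coefficient **is** the log2 fold
change; the published cutoff (>1.2 or <−1.2, strict) applies directly to
it, together with BH-adjusted p < 0.05. BH is applied within each
comparison across all tested proteins. Two separate two-group models are
fitted (all-AD vs HC; cluster 1 vs cluster 2) rather than one three-level
model, matching the two published comparisons.

**Empirical-Bayes moderation.** Residual variances are modeled as
scaled-chi-square draws around a prior (d0, s0²) estimated by the method
of moments on log variances: with z_g = log s²_g and e_g = z_g −
ψ(d_g/2) + log(d_g/2), the prior df solves ψ′(d0/2) = Var(e) − mean
ψ′(d_g/2) by Newton inversion of the trigamma function; a non-positive
right-hand side (no excess dispersion) yields d0 = +∞ and full pooling.
The posterior variance s̃² = (d0·s0² + d·s²)/(d0 + d) feeds the
moderated t on d0 + d degrees of freedom. `d0_override` exposes the
limits: 0 recovers the ordinary t, +∞ a pooled-variance statistic. The
estimator is validated in the test suite against the Bioconductor limma
reference on a shared fixture.

The Venn trichotomy partitions the two upregulated sets into *stepwise*
(both contrasts), *unique* (cluster contrast only) and *upregulated-AD*
(all-AD contrast only). The mean–variance diagnostic is exported as a
table (mean NPX vs log s²); no automated decision is taken on it.

## Co-expression network

**Soft power.** For each integer β in 1..20, the signed adjacency
a_jk = ((1 + cor_jk)/2)^β is built and the scale-free fit computed:
connectivities k_i = Σ_{j≠i} a_ij are binned into 10 equal-width bins and
log10 frequency is regressed on log10 mean connectivity; R² counts only
when the slope is negative. The selected power is the lowest β reaching
R² ≥ 0.9. When no power reaches the target (block-factor data with
homogeneous within-module connectivity typically does not look
scale-free), a plateau rule applies: the smallest β within 0.02 of the
best R², logged with a warning — the curve saturates well before its
argmax, and a boundary power would wash out weaker modules.

**TOM and modules.** The signed topological overlap is
tom_jk = (ℓ_jk + a_jk)/(min(k_j, k_k) + 1 − a_jk) with ℓ_jk = Σ_u a_ju
a_uk (u ≠ j, k). Modules are detected on 1 − TOM by average-linkage
clustering cut at the 0.99 quantile of merge heights; branches below 20
proteins fall to "grey" (unassigned); grey proteins whose best kME
reaches 0.3 are rescued into that module; modules whose eigenproteins
correlate above 0.75 are merged iteratively. This static
cut/size/rescue/merge scheme is a transparent stand-in for hybrid
dynamic tree cut with all four knobs exposed in config. Final modules
are named by the conventional color sequence, largest first.

**Eigenproteins and hubs.** A module eigenprotein (ME) is the first
principal component of the z-scaled member submatrix, oriented to
correlate positively with the module's average profile. kME is the
Pearson correlation of **every** protein with each ME (not members only),
which is what enables the rescue step and hub neighborhoods; the hub is
the member with the highest own-module kME. Module–trait association is
the Pearson correlation of each ME with each numeric trait
(pairwise-complete, two-sided t-transform p), BH-adjusted over the whole
module × trait grid; by default it is computed on patients only, with an
all-samples switch. Binary traits are coded 0/1.

**Hub graphs.** Each module's graph unions its DE proteins with the
top-30 proteins by adjacency to the hub ("most strongly correlated" is
read as adjacency, the stated edge-length source). Edges carry adjacency
weights (downstream layouts use 1/weight as length); an optional
adjacency-quantile floor prunes the near-complete graph for export, and
defaults to 0 to reproduce the construction exactly.

## Enrichment

Preranked GSEA scores each protein by its Pearson correlation with a
module's ME (ties broken by protein id). The enrichment score is the
classic weighted Kolmogorov–Smirnov running statistic (weight exponent 1;
hits add |score|/Σ|score over hits|, misses subtract 1/(N−K)); the null
is 1,000 seeded draws of random same-size sets from the universe —
a gene-set permutation null, chosen because a preranked analysis has no
sample labels to permute — with p = (1 + #{same-side |ES⁰| ≥ |ES|})/(1 +
nperm) and NES = ES / mean same-side |ES⁰|. Overrepresentation uses the
upper-tail hypergeometric test with the universe fixed to all assayed
proteins. Protein-to-symbol mapping defaults to the identity, with an
optional two-column translation table; gene sets arrive as GMT.

## Clinical model

The random forest (500 trees, sqrt-p features, bootstrap) predicts
cluster membership from clinical variables; categorical inputs are
one-hot encoded and missing values median-imputed. Mean decrease in
accuracy is computed on out-of-bag samples: per-tree OOB membership is
reconstructed by replaying the bootstrap draw from each tree's random
state, and the OOB majority-vote accuracy drop under per-feature
permutation is reported alongside Gini impurity importance, with ranks
for both. Out-of-bag accuracy (not cross-validation) summarises fit.
The threshold scan reports per-cluster extrema and either a clean
separating value (one cluster's max below the other's min) or the best
single-split threshold by accuracy. Group comparisons use the two-sided
Wilcoxon rank-sum test (exact enumeration when both groups ≤ 10 with no
ties, tie-corrected normal approximation otherwise) for numeric
variables and Pearson's chi-squared (no Yates correction by default; a
flag enables it) for categorical ones.

## Synthetic cohorts: what they emulate, and what they do not

The generator draws x_ij = μ_j + λ_j f_mi + e_ij with per-module latent
factors f ~ N(0,1), loadings λ ~ U(0.6, 0.85), noise sd 0.6 NPX and
baselines μ ~ U(2, 10) NPX; background proteins carry no factor. Group
structure enters through (i) the disease (first) module's factor, whose
mean is shifted by +1.35 (cluster 1) and +0.35 (cluster 2) with a tight
within-group sd of 0.18 — encoding that endotype membership explains
most of the disease-module activity, which is what makes the planted
endotypes recoverable by k-means in 1,248 dimensions; (ii) a +1.8 NPX
shift (±20% per-protein jitter) on the 169 AD-up proteins for all
patients; and (iii) additional +3.0 NPX shifts on the 40 stepwise and 16
unique proteins for cluster-1 patients, the scale of canonical
inflammatory markers. These values were chosen jointly so that the
planted structure is recoverable while the two DE contrasts yield
approximately the published set sizes (169 and ~56 upregulated proteins)
rather than sweeping whole modules over the fold-change cutoff; they are
calibrated conventions, not estimates from data.

Clinical traits are drawn per group from normal models with the
published cohort means/SDs where printed (e.g. EASI 37.7/12.2 vs
26.9/9.8; eosinophils 1.1/0.8 vs 0.4/0.2), clipped to physiological
ranges, with disease-severity traits additionally coupled to the disease
module's factor. Coupling coefficients are generator conventions — the
source cohort publishes no within-group marker–trait correlations to
calibrate against.

All randomness flows from one seed through fixed, named substreams, so
adding a trait does not perturb protein draws and identical seeds give
bitwise-identical cohorts.

The generator does **not** emulate: Olink plate/batch effects, LOD
censoring, heavy-tailed or skewed marginals, hub-like heterogeneous
connectivity within modules (within-module connectivity is roughly
homogeneous, which is why the scale-free fit rarely reaches R² = 0.9 on
simulated data and the plateau fallback engages), missingness,
longitudinal flare dynamics, or treatment effects. Passing recovery
tests on these cohorts therefore demonstrates the pipeline's
correctness under its stated assumptions — linear co-expression,
Gaussian noise, endotype-dominated disease-module activity — not its
behavior under real-world assay artifacts.

**Benchmark instance.** The reproducibility benchmark cohort is 73
patients (31/42), 1,248 proteins, no co-expression blocks, and exactly 40
informative markers shifted two within-cluster standard deviations
(Cohen's d = 2). A structural note: after per-protein z-scaling a
marker's between-cluster gap is bounded by 1/√(p₁p₂) scaled units, so
with 40 informative dimensions out of 1,248 the testing part (n = 22) of
the split protocol operates near the k-means recovery threshold
regardless of how large the planted shift is; median testing accuracy
in the high-80s is the expected operating point of this protocol on such
data, while training accuracy saturates at 100%.

## Numerical choices and degenerate inputs

- WCSS monotonicity in k is asserted to a tolerance of 1e−8 × total SS
  (best-of-restarts is not exactly monotone).
- Empty k-means clusters are re-seeded by the underlying solver.
- Zero-variance proteins: correlations set to 0 in the network (warning),
  score 0 in GSEA ranking (warning), zeros after z-scaling (warning).
- p_adj = 0 is clipped to the smallest positive double before −log10.
- The trigamma inversion uses Newton steps from x = 0.5 + 1/y, tolerance
  1e−10, following the standard approach for this equation.
- Degenerate eigenprotein submatrices yield a zero ME and a flagged
  module.
- Exact Wilcoxon switches to the normal approximation in the presence of
  ties at any sample size.

## Problem sizes used by the test suite

Unit tests run on hand-sized fixtures (≤ 60 samples, ≤ 300 proteins).
Recovery and calibration tests use the full default cohort (88 × 1,248);
the endotype-recovery median uses 20 independent cohorts, the null
calibration 20 null cohorts, and module recovery a single cohort (the
module pipeline is deterministic given the cohort). The reproducibility
benchmark runs its full 100 iterations. Pipeline-integration tests use a
reduced cohort (36 × 120, three modules) to keep the end-to-end path
fast.

## Known limitations

- The static quantile cut is cruder than hybrid dynamic tree cut; on
  real data with nested module structure the exposed knobs
  (cut quantile, minimum size, kME rescue, merge height) may need tuning.
- The moment estimator for (d0, s0²) assumes roughly independent
  residual variances; strong co-expression inflates its sampling
  variance (it remains consistent).
- GSEA's gene-set permutation null ignores inter-protein correlation and
  is anti-conservative on strongly correlated modules; the module-level
  conclusions here rest on the ORA route as well.
- The clinical RF reports OOB-based importance only; no external
  validation or calibration is implemented.
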