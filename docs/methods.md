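# Methods

## The synthetic multi-cohort generator

The generator emulates the statistical situation a multi-cohort tumor
expression integration faces: several cohorts measure the same biological
subtypes, but each cohort's processing adds its own per-gene distortion,
and clinical follow-up is right-censored.

On log2 scale, expression of gene *g* in sample *s* of cohort *c* is

    y_gsc = μ_g + β_k·1[g ∈ sig(k)] + γ_gc + δ_gc·ε_gs,   ε ~ N(0, σ²)

with per-gene baselines μ_g ~ N(4, 2²) (a realistic spread of log2
abundances), disjoint subtype signature blocks with effect β_k,
additive cohort offsets γ_gc ~ N(0, τ_b²) and positive multiplicative
factors δ_gc drawn from an inverse-gamma with mean ≈ 1 that scale the
noise term. FPKM-scale values are 2^y, so matrices are strictly positive.
This is exactly the location/scale model the empirical-Bayes correction
stage assumes, which makes correction testable as parameter recovery: the
truth ledger stores every γ, δ, signature gene and survival parameter.

Defaults (the package's study conditions): 2 cohorts × 3 subtypes ×
100 samples, 2000 genes, 50 signature genes per subtype at 2.0 log2 units,
noise σ = 1.0, batch offset spread τ_b = 1.8, δ² ~ InvGamma(20, 19).
τ_b = 1.8 makes the cohort label explain ≈ 40% of per-gene variance
(averaged over genes, one-way ANOVA R²) — a dominant batch signal of the
kind integration projects report — while the subtypes remain separable
after correction. The mean-of-ratios R² statistic is noticeably smaller
than the ratio-of-means one because per-gene offsets are χ²-skewed; the
default was chosen against the measured statistic.

Survival is Weibull per subtype, parameterized by median m and shape k
(scale = m / ln2^{1/k}); defaults are exponential (k = 1) with medians
{1, 3, 8} years, matching the ordering of IDH-wildtype glioblastoma,
astrocytoma and oligodendroglioma. Survival is independent of expression
given subtype, so the neighbor-median annotation has an unambiguous truth:
the subtype median. Censoring is an independent exponential clock; its
single global rate is solved by Brent root-finding so the mixture-averaged
censoring probability ∫(1−e^{−ct})f_T(t)dt equals the requested fraction
(default 0.2). At rate 0 the clock is infinite and recorded times equal
event times exactly.

Overlay events (mutation, fusion, copy-number gain/loss) are Bernoulli per
(sample, gene) with a small background probability everywhere and an
elevated probability on the sample's own subtype-signature genes, so
event frequencies are subtype-enriched with known rates. Copy-number calls
use the five-level GISTIC vocabulary {−2..2}; a gene is gained or lost in
a sample, never both. Fusions carry high/medium/low confidence (70/15/15%)
so the high-confidence filter has work to do.

One `numpy.random.SeedSequence` spawns a fixed per-stage seed list
(baseline, batch, noise, survival, censoring, overlays), so outputs are
bit-reproducible from (config, seed) and changing one stage's draws cannot
shift another's.

What the generator does **not** emulate: count-level noise
(negative-binomial mean-variance coupling), gene-gene correlation beyond
the subtype signatures, expression-survival coupling within a subtype,
informative censoring, or library-composition artifacts. Passing recovery
tests therefore demonstrates the statistical machinery is correct under
its own model, not that real cohorts satisfy that model.

## Harmonization

TPM conversion divides each sample by its own total and rescales to 10⁶;
it is exact, idempotent on normalized input, and refuses all-zero samples.
Cohorts are intersected to (universe ∩ ∩ᵢ genesᵢ) in universe order.
log2(TPM + pseudocount) with pseudocount 1 precedes correction — the EB
location/scale model assumes roughly Gaussian data, and pseudocount 1 maps
zero to zero.

`correct_batch` implements the parametric ComBat procedure: standardize
each gene by its weighted-batch-mean grand mean and pooled residual
variance; estimate per-batch per-gene location γ̂ and scale δ̂²; fit a
normal prior to the γ̂ and an inverse-gamma prior to the δ̂² by moment
matching within each batch; iterate the joint conditional-posterior
updates to tolerance 1e-4 (max 100 iterations; typically 3–5 suffice);
adjust and restore the global location/scale. `mean_only` centers batch
means without scale adjustment or shrinkage, and accepts a single batch as
an identity operation. Zero-variance genes are passed through untouched
and listed in the report, keeping the gene universe stable across stages.
`location_prior_var` optionally overrides the fitted prior variance; a
very large value disables location shrinkage, which is how the
shrinkage-off limit is verified. The implementation agrees with scanpy's
ComBat to ~5e-4 on shared instances (a cross-check in the test suite).

No biological covariates enter the correction design. With confounded
designs this risks over-correction; the simulated designs are balanced, so
the tests do not probe that failure mode and real-data users should
balance cohorts per subtype where possible.

## Landscape and classification

PCA is computed internally by exact SVD on gene-centered data, with
component signs fixed deterministically; it preserves pairwise distances
at full rank and is the exactly-testable reducer. UMAP/t-SNE are delegated
to their reference implementations through a pluggable registry with the
seed forwarded; their coordinates are implementation-defined, so they are
validated only through concordance metrics (silhouette, ARI of k-means
with k = number of label levels).

Neighbor queries are exact exhaustive scans: Euclidean distance, boundary
inclusive (d ≤ r), the query excluded, ties broken by (distance, sample
id). At the landscape sizes this package targets (10²–10⁴ samples) a
spatial index buys nothing, and exactness lets a brute-force oracle pin
the semantics. Classification takes the k nearest labeled samples and
majority-votes; vote ties fall back to summed inverse distance, then
lexicographic label order — every rule deterministic so predictions are
invariant to input permutation and rigid motion of the coordinates.

## Survival annotation

Non-primary (recurrent/secondary/normal) samples are removed first, then
one sample per patient is kept (the lexicographically smallest id), with
every exclusion logged. Kaplan-Meier estimation is backed by lifelines and
exposed as a plain step-function table with at-risk/death/censored counts
and Greenwood variance (computed, but no inference is built on it). The
median is the smallest *event* time with S(t) ≤ 0.5 and is explicitly
undefined when the curve never reaches 0.5 — the definition under which
"undefined median" is meaningful.

For annotation, each sample's stratum is every landscape sample sharing
its subtype and dataset (configurable). Candidates are stratum members
within the radius (default 2 embedding units); the neighbor cohort is the
⌊fraction × stratum size⌋ nearest of them, where the stratum count
includes the index sample but the neighbor set never does — a sample's own
survival time cannot enter its own prediction. Fewer than `min_neighbors`
(default 10) neighbors, or an undefined neighbor-cohort median, leaves the
sample unannotated. The radius and the fraction rule are composed as "the
k nearest among those within the radius"; both constraints exist
independently in the field's usage and this composition is the recorded
interpretation. The radius is meaningful only relative to the embedding's
scale, so a warning fires when it exceeds 25% of the landscape diameter.
Whether the 25% denominator includes the index sample and whether the
radius test is inclusive are both genuinely open conventions; both are
config-visible (`neighbor_fraction`, and the inclusive boundary is pinned
by the oracle tests).

Under the default conditions (stratum 100, k = 25 exponential survival
times), the annotation's median absolute relative error against planted
medians is dominated by the sampling noise of a 25-sample KM median
(relative sd ≈ 0.29) plus per-stratum drift; it lands around 15–25%.

## Pathway scoring and testing

The scorer is a rank-only two-sided KS running sum: genes ranked within
each sample (average ranks for ties), the list walked from highest to
lowest expression; an in-set gene steps the sum up by its normalized
weight |rank − (N+1)/2| (τ = 1), an out-of-set gene steps down uniformly
by 1/(N−m); the score is the maximum positive plus minimum negative
excursion, guaranteed in [−1, 1] (clamped against float accumulation).
Being rank-only it is invariant to any strictly monotone per-sample
transform and to gene order. It is deliberately simpler than
kernel-density GSVA — no Gaussian-kernel ECDF smoothing — because the
simpler statistic is exactly testable; the scoring backend is a pluggable
method tag, so a full GSVA implementation can be substituted. Set-size
bounds default to [5, 500].

The moderated t follows the standard empirical-Bayes variance-shrinkage
construction: per-set pooled two-group variance s², prior (d₀, s₀²)
estimated by moment-matching the scaled-F distribution of log s² (digamma/
trigamma inversion by Newton iteration), posterior
s̃² = (d₀s₀² + d·s²)/(d₀ + d), and t = Δmean/(s̃√(1/n₁+1/n₂)) on d₀ + d
degrees of freedom. The implementation reproduces R limma's eBayes to
seven significant digits on a frozen fixture. d₀ = 0 recovers the ordinary
pooled t; d₀ → ∞ uses s₀² for every set. Multiple testing is
Benjamini-Hochberg within one contrast (a conventional default; nothing
here depends on it structurally). Only two-group contrasts are supported;
multi-level designs are out of scope. `shared_regulated` intersects
significant same-direction sets across contrast tables over the same
collection.

## Interchange formats and the pipeline

All formats are plain TSV/JSON: expression (genes as rows, first column
the gene id), metadata, MAF-like mutation rows (canonicalized to
sample/gene/variant-class, full duplicates collapsed), fusion rows with a
{high, medium, low} confidence vocabulary and a retain-filter that logs
removals, GISTIC-style copy-number matrices validated against {−2..2},
landscape TSV+JSON with a SHA-256 provenance digest of the input matrix,
and GMT gene sets. Identifiers are opaque strings matched exactly; symbol
aliasing is a curation concern upstream of this package. Mutation burden
counts rows (one per sample/gene/variant-class), not genes; a gene matches
a fusion as either partner.

Each pipeline stage writes a JSON manifest with its parameters, seed and
input/output digests. Floats are serialized at %.17g, so a rerun with the
same config and seed is byte-identical — verified end to end in the tests.

## Problem sizes

The default scenario (600 samples × 2000 genes) runs the full pipeline in
about a minute on one CPU; unit tests use a 180 × 400 variant of the same
scenario. Monte-Carlo checks of survival medians use up to 2000 draws per
group so that 10% tolerance bands sit ≥ 3 sampling standard deviations
from the truth; the moderated-t calibration uses 5000 null sets at
n = 20 + 20.

## Known limitations

- The EB correction assumes the generator's own location/scale model;
  latent-factor batch structure (RUV/PEER-style) is out of scope.
- Nonlinear embeddings are seeded but implementation-defined; only PCA has
  exact guarantees.
- The annotation transfers survival through embedding proximity within
  strata; with survival independent of expression given subtype (as
  simulated), its accuracy ceiling is the stratum median — finer-grained
  survival structure within a subtype would require expression-survival
  coupling the generator does not model.
- Cox models, log-rank tests and confidence bands are deliberately not
  provided.
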