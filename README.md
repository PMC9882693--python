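# brainscape

Build survival-annotated transcriptomic reference landscapes from multiple
bulk RNA-seq cohorts.

Large tumor-expression resources (adult glioma, pediatric brain tumors,
healthy brain) are quantified by different pipelines in different units and
carry strong cohort-specific batch effects. `brainscape` implements the
full integration path a reference-landscape study needs — unit
harmonization, batch correction, embedding, nearest-neighbor survival
annotation, single-sample pathway scoring with moderated-t contrasts, and
gene-level genomic overlays — and ships a synthetic multi-cohort generator
with known ground truth so every stage can be validated as parameter
recovery. It is aimed at computational biologists who integrate public
expression cohorts (TCGA/CGGA/GTEx-like) and want the statistical
machinery testable end to end before pointing it at real data.

## What it computes

**Harmonization.** FPKM is converted to TPM per sample,
`TPM_gs = FPKM_gs / Σ_g FPKM_gs × 10⁶`, cohorts are intersected to a common
gene universe, log2(TPM+1) is taken, and per-cohort batch effects are
removed with a ComBat-family empirical-Bayes location/scale model: per-gene
per-batch additive effects γ_gb and multiplicative effects δ_gb are
estimated on standardized data, shrunk toward moment-matched priors
(normal for γ, inverse-gamma for δ²) by the standard joint fixed-point
iteration, and subtracted/divided out.

**Landscape.** 2D/3D embeddings by exact PCA (internal SVD) or seeded
UMAP/t-SNE; exact brute-force neighbor queries (inclusive radius,
deterministic tie-breaks); k-nearest-neighbor subtype classification of
unlabeled samples.

**Survival annotation.** After removing recurrent/secondary/normal samples
and keeping one sample per patient, each sample is colored with the
Kaplan-Meier median survival of a neighbor cohort: stratum members (same
subtype and dataset) within radius 2, the nearest `⌊0.25 × stratum⌋` of
them; samples with fewer than 10 neighbors, or whose neighbor curve never
reaches S(t) ≤ 0.5, stay unannotated. The product-limit estimator is
`S(t) = Π_{t_i ≤ t} (1 − d_i/n_i)`.

**Pathways.** Each sample is scored against GMT gene sets with a rank-only
two-sided KS running-sum statistic in [−1, 1]; two-group differences are
tested per set with a moderated t, `s̃² = (d₀s₀² + d·s²)/(d₀ + d)` on
`d₀ + d` degrees of freedom with `(d₀, s₀²)` moment-matched across sets,
and Benjamini-Hochberg adjustment; significant sets can be intersected
across contrasts.

**Overlays.** Per-sample mutation/fusion burdens, copy-number gain/loss
counts from GISTIC-style {−2..2} tables, and per-gene joins of expression,
mutation, fusion and copy-number status onto the landscape.

## Worked example

The default scenario: two cohorts × three subtypes × 100 samples each,
2000 genes, planted batch effects, exponential survival with medians
{1, 3, 8} years and ~20% censoring.

```sh
python analysis/01_simulate.py          --outdir results/run --seed 0
python analysis/02_harmonize.py         --outdir results/run --seed 0
python analysis/03_embed.py             --outdir results/run --seed 0
python analysis/04_annotate_survival.py --outdir results/run --seed 0
python analysis/05_pathways.py          --outdir results/run --seed 0
python analysis/06_genomic_overlays.py  --outdir results/run --seed 0
```

prints, among other things:

```
mean per-gene variance explained by cohort after correction: 0.001%
umap landscape: 600 samples, diameter 20.35
subtype silhouette 0.930, k-means ARI 1.000
annotated 100.0% of 600 samples
median |relative error| vs planted medians: 14.8%
  astrocytoma: KM median 2.70 y (planted 3.0) over n=200
  idh_wildtype: KM median 0.91 y (planted 1.0) over n=200
  oligodendroglioma: KM median 9.15 y (planted 8.0) over n=200
withheld-label recovery: 100.0% of 60 samples
```

Reading this: the correction removed essentially all cohort-driven
variance while the subtypes remain cleanly separated on the landscape
(silhouette 0.93); every sample received a neighbor-cohort survival
estimate, and those estimates sit within ~15% of the planted subtype
medians; k-NN classification recovers all withheld subtype labels.

The same stages are available as one CLI over a single config:

```sh
brainscape pipeline -c config.yaml -o results/run        # or stage by stage:
brainscape simulate -o results/run --seed 0
brainscape harmonize -o results/run
...
```

Each stage writes a JSON manifest (parameters, seed, input/output SHA-256
digests); rerunning with the same config and seed reproduces every output
byte for byte.

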