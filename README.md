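# compartmentseq

Toolkit for comparing cell type-specific RNA-seq across subcellular capture
methods: nuclear-FACS, whole cell-FACS, and ribosome-bound affinity
purification (RiboTag-style), applied to two closely related neuronal
populations (D1- and D2-type medium spiny neurons).

The three methods sample different RNA pools of the *same* cells — nuclear
(transcription), whole-cell (steady state), ribosome-bound (translation) —
so a head-to-head comparison must disentangle genuine cell-type biology
from method-induced bias. `compartmentseq` implements the full comparison
pipeline as a library of scikit-learn-style estimators plus a synthetic-data
generator with planted ground truth, so every stage is testable without any
sequencing data:

* **Quantification & filtering** — FPM / FPKM, intron fractions
  (all-feature minus exon-only counts), median-of-ratios size factors, a
  `log2(count/sf + 1)` variance-stabilizing transform, a detection filter
  (> 1 FPM in ≥ 2 samples) and method-specific final FPKM filters (≥ 1 in
  ≥ 1 sample for nuclear / whole cell, ≥ 0.1 in ≥ 2 for ribosome-bound,
  ≤ 5×10⁴ everywhere).
* **Differential expression** (`NegativeBinomialDE`) — per-gene NB GLM Wald
  test of D1 vs D2 with moment/trend-shrunk dispersions; the DEG cascade
  |log2FC| > 0.38 (a 30% change), BH-adjusted p ≤ 0.05, baseMean above the
  within-method 25th percentile, and removal of nuclear DEGs in the top
  quartile of the fold-change standard error; cross-method overlap sets and
  a logistic regression of overlap status on DE features.
* **Cross-compartment regulation** (`CompartmentRegulationClassifier`) — a
  joint NB GLM over all three compartments whose contrasts decompose the
  cell-type difference along the nucleus → cytosol → ribosome cascade into
  transcriptional, cytosolic and translational regulation, with per-category
  BH adjustment, directions, and pattern/dominance summaries.
* **Variance partitioning** (`VariancePartitioner`) — per-gene REML variance
  components for method, cell type and residual; argmax categorization;
  assignment of method-variable genes by peak FPKM; subcellular-localization
  set composition.
* **Networks** (`CoexpressionNetwork`, `MutualInformationNetwork`) — signed
  weighted co-expression networks (biweight midcorrelation, scale-free soft
  power, signed TOM, static-cut module detection with eigengene merging and
  kME pruning, eigengene–trait correlation with Bonferroni thresholds), an
  ARACNE-style mutual-information network (equal-frequency discretization,
  data-processing-inequality pruning), their consensus edge set, and top-20
  hub networks with first-degree neighbors.
* **Enrichment** — two-sided Fisher's exact gene-set tests over a declared
  background, plus GWAS-catalog preparation: strict p < 5×10⁻⁸ lead-variant
  filtering, intergenic exclusion, orthologue mapping and trait curation.
* **PCA distances** (`ExpressionPCA`) — sample PCA, method centroids on
  PC1/PC2, within-method distances and Welch t-tests, outlier flagging.

## Worked example

```python
import compartmentseq as cs

cfg = cs.SimConfig(n_genes=1200, seed=11)
exon, counts, annotation, truth = cs.simulate_experiment(cfg)

frac = cs.intron_fraction(counts, exon)
print(frac.mean(axis=0).groupby(counts.metadata["method"]).mean().round(3))

final, _ = cs.final_filter(*cs.detection_filter(counts.subset_method("ribotag"))[:1],
                           annotation, "ribotag")
called = cs.NegativeBinomialDE().fit(final).call("ribotag")
degs = called[called["enrichment_call"] != "none"]
planted = set(truth.deg_labels["ribotag"])
print(len(degs), "DEGs called,", len(set(degs.index) & planted), "planted")
```

prints

```
method
nuclear      0.45
ribotag      0.08
wholecell    0.25
dtype: float64
169 DEGs called, 161 planted
```

— the planted intron-share ordering (nuclear > whole cell > ribosome-bound)
is recovered exactly, and 161 of the 169 ribosome-bound DEG calls are
planted cell-type effects (the cascade controls the false discoveries).
The PCA stage on the same experiment gives

```
mean within-method distance on PC1/PC2:
nuclear      2.31
ribotag      0.64
wholecell    3.38

Welch t-test nuclear vs ribotag within-method distances: p = 1.36e-07
```

— the ribosome-bound libraries cluster most tightly while sitting farthest
from the other two methods, the method-comparison signature the pipeline is
designed to expose.

A thin CLI mirrors the library
(`compartmentseq simulate|filter|de|regulation|varpart|pca|network|enrich`).

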