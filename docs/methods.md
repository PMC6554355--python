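# Methods

This note documents the statistical models, numerical choices and
limitations of `compartmentseq`. Everything quantitative stated here is
recomputed by the test suite or by `scripts/acceptance.py`; nothing is a
stored result.

## The comparison problem

Three isolation methods sample different RNA pools of the same two cell
types: nuclear-FACS captures (intron-rich, non-coding-rich) nascent and
nuclear-retained RNA; whole cell-FACS the steady-state transcriptome; and
ribosome-bound affinity purification the actively translated, strongly
protein-coding fraction with a pronounced low-expression tail for
everything else. The pipeline quantifies what each method sees (filters,
biotype composition, intron share), what it says about cell-type identity
(differential expression, co-expression), and how much of the observed
variance is method rather than biology (variance partitioning, PCA
distances). A cross-compartment GLM then uses all three methods jointly to
attribute cell-type differences to transcriptional, cytosolic or
translational regulation.

## Synthetic data generator

The generator is the test bed: it draws NB counts whose mean structure
contains every effect the pipeline is meant to detect, and returns the
planted truth.

Counts for gene *g* in sample *s* are negative binomial with
Var = μ + α·μ², α per gene lognormal (median 0.05, log-sd 0.5 by default),
via gamma–Poisson mixing from one PCG64 stream
(`numpy.random.default_rng(seed)`); a fixed seed reproduces the matrices
bit for bit. The mean is assembled multiplicatively:

    μ_gs ∝ baseline_g × method_weight_g(m) × 2^(planted log2 effects + jitter_gs)

then rescaled per sample so column totals match a library size drawn
uniformly from `library_size_range` (exercising size-factor normalization).
All-feature counts are thinned binomially into exon-only counts with a
method-dependent intron probability (expected shares 0.45 / 0.25 / 0.08 for
nuclear / whole cell / ribosome-bound, modulated per gene), which guarantees
all ≥ exon elementwise and plants the intron-share ordering.

Default conditions (the emulated study design):

| knob | default | rationale |
|---|---|---|
| samples | 16 whole-cell (9 D1 / 7 D2), 11 nuclear (6/5), 12 ribosome-bound (6/6), male | the study layout |
| genes | 2 000 | desk scale; every stage runs in minutes |
| baseline mean | lognormal(3.0, 1.3) (natural log) | wide dynamic range |
| dispersion α | lognormal(log 0.05, 0.5) | typical bulk biological replicates |
| ribosome-bound non-coding weight | 0.1 | strong coding bias of ribosome capture |
| ribosome-bound short-gene (< 500 bp) weight | 0.5 | length bias of ribosome capture |
| nuclear non-coding weight | 2.0 | nuclear retention of regulatory RNA |
| per-method log2 technical jitter | 0.5 / 0.35 / 0.05 | the observed within-method variance ordering (nuclear ≫ whole cell ≫ ribosome-bound) |
| planted DE | 15% of genes per method at &#124;log2FC&#124; = 1 | detectable but not trivial at n ≈ 6/group |
| DE non-coding sampling bias | 2.0 / 1.0 / 0.25 | nuclear cell-type differences extend across non-coding biotypes; ribosome-bound ones concentrate in coding RNA |

The capture efficiencies are tunable stand-ins, not estimates from any
dataset: no quantitative compartment efficiencies are published for this
design, so the defaults were chosen once to reproduce the qualitative
method signatures robustly across seeds and are not revisited per run.

Regulation categories are planted as cell-type shifts in the compartments
*downstream* of the regulated step — transcriptional: nuclear + whole cell
+ ribosome-bound; cytosolic: whole cell + ribosome-bound; translational:
ribosome-bound only — so each category loads on exactly one contrast of the
regulation GLM (a closed recovery loop). Co-expression blocks add a shared
per-sample latent factor on the log scale; with loading λ and unit noise
the expected within-block correlation is λ²/(λ²+1) (λ = 2 → r ≈ 0.8).

What the generator does **not** emulate: read-level artifacts (FASTQ, UMIs,
mapping), batch effects beyond method, single-cell dropout, correlated
gene–gene noise outside planted blocks, and realistic transcriptome size —
at 2 000 genes with ~10⁶ fragments the per-gene coverage is far above real
data, so the low-FPKM filters remove little at desk scale (their logic is
exercised on enumerated fixtures instead). Passing tests therefore
demonstrate correctness of the estimators under the stated noise model, not
performance on real libraries.

## Filtering cascade

Detection keeps genes with FPM strictly > 1 in ≥ 2 samples (an `inclusive`
flag switches to ≥, since both conventions appear in practice). Final
filters are method-specific: FPKM ≥ 1 in ≥ 1 sample (nuclear, whole cell)
or ≥ 0.1 in ≥ 2 samples (ribosome-bound, whose libraries have a genuine
low-expression tail), plus a common cap of 5×10⁴ FPKM in every sample that
removes over-amplification artifacts. FPM/FPKM denominators always use the
unfiltered library totals, so filtering never changes the scale. The
variance-stabilizing transform is a documented stand-in,
`log2(count/size_factor + 1)`: deterministic, dependency-free, monotone
within sample, and adequate as PCA/variance/co-expression input; it is not
a fitted mean–dispersion transform.

## Differential expression engine

A deliberately simple, fully specified NB engine (no fold-change shrinkage,
no outlier replacement):

1. **Dispersion.** Per gene, a method-of-moments estimate from the pooled
   within-group variance of size-factor-normalized counts,
   α̂ = (v − μ·E[1/s]) / μ², floored at 10⁻⁸, then shrunk toward a lowess
   trend of log α̂ on log μ by averaging raw and trend on the log scale.
   Two small-sample corrections keep the estimator unbiased where it is
   used: v is rescaled by exp(−(ψ(d/2) − log(d/2))) (the E[log χ²_d] offset,
   since the shrinkage operates on the log scale), and the denominator
   subtracts Var(μ̂) ≈ v/n. Without them the downstream Wald test is
   measurably anticonservative at n = 6 per group.
2. **Wald test.** Per gene, an NB GLM with log link, design
   intercept + cell type, offset log size factor, fixed α̂; log2FC is the
   natural-log coefficient / ln 2, p two-sided normal, BH across all tested
   genes. Non-convergent fits are flagged and excluded from the family.
3. **DEG cascade.** |log2FC| > 0.38 (strictly; 0.38 = log2(1.3), a 30%
   change), p_adj ≤ 0.05, baseMean above the within-method 25th percentile;
   nuclear calls additionally drop the top quartile of lfcSE *among called
   DEGs*, countering the nuclear pool's excess variance.

Calibration (recomputed by the acceptance script): at n = 6/group,
μ = 100, α = 0.1, the null type-I error at p ≤ 0.05 stays within the exact
binomial 99% CI of 0.05 and the planted unit log2FC is recovered with
|bias| ≪ 0.2.

## Cross-compartment regulation GLM

One NB GLM per gene over all 3 × 2 groups:
`compartment + cell_type + compartment:cell_type` (nuclear and D2 as
references), IRLS to tolerance 10⁻⁸, ≤ 100 iterations. The contrasts

* transcriptional = cell-type effect (the nuclear contrast),
* cytosolic = whole-cell:cell-type interaction,
* translational = ribosome:cell-type − whole-cell:cell-type,

are the unique decomposition of the per-compartment cell-type differences
along nucleus → cytosol → ribosome; by construction transcriptional +
cytosolic equals the whole-cell contrast exactly. Each contrast is tested
by Wald z from the coefficient covariance, BH-adjusted within category
(three families), with direction from the sign. Dispersion is shared with
the DE estimator, computed across all six groups.

A power ceiling is worth stating plainly: with Var = μ + αμ² the variance
of a contrast spanning four group means is at least 4α/n even at infinite
expression. At α = 0.1 and n = 6 that is an SE of 0.258, so an ln 2 effect
gives z ≈ 2.7 and BH-level sensitivity of roughly 0.4–0.5 for the cytosolic
and translational categories (≈ 0.85 for the transcriptional contrast,
whose SE floor is √(2α/n)). Reaching 90% sensitivity on the interaction
categories at this effect size requires n ≳ 13 per group. The acceptance
script reports the measured sensitivities as they are.

## Variance partitioning

Per gene, a grand mean plus two crossed random intercepts (method, cell
type) with residual noise. Variance components are estimated by exact REML:
because the random-effect covariance is constant within each
(method, cell type) group, the data collapse to G = 6 scaled group means
plus N − G within-group contrasts, and each likelihood evaluation needs
only 6×6 linear algebra (Nelder–Mead on log-variances; ANOVA
method-of-moments start doubles as the fallback estimate). Negative
components are truncated at zero before normalization, so the three
fractions lie in [0, 1] and sum to one. Near-constant genes are flagged
with missing fractions. Categorization is argmax with the fixed tie-break
residual > method > celltype. Note that variance components measure
superpopulation (ddof = 1-style) level variance: a two-level factor with
levels ±c carries component 2c², not c².

## Networks

The co-expression arm follows the WGCNA recipe with deterministic
replacements for its heuristic steps:

* **bicor** with tuning constant 9 MADs and weight truncation; zero-MAD
  genes fall back to Pearson (logged).
* **Soft power** chosen as the smallest β ∈ 1..20 whose signed adjacency
  ((1+r)/2)^β gives scale-free fit R² > 0.8; the fit index is the log–log
  histogram regression R² carrying the sign of −slope (the standard
  convention — without the sign, distributions with frequency *increasing*
  in connectivity pass spuriously and β = 1 gets selected). If no candidate
  passes, the R²-maximizing β is used with a warning. The published powers
  (pooled 18, nuclear 12, whole cell 18, ribosome-bound 9, with-female 6)
  are kept as defaults for matching tranches; planted-block experiments use
  the fixed pooled power 18, because a two-block toy is genuinely not
  scale-free and auto-selection would be an arbitrary argmax.
* **Signed TOM**, average-linkage clustering on 1 − TOM with a static cut
  at 0.99, minimum module size 100, iterative merging of eigengene pairs
  with r > 0.8 (merge height 0.2), kME pruning at |kME| < 0.1, and no
  post-assignment of unclustered genes (module labels are deterministic).
* **Eigengenes** are the first right-singular vector of the
  gene-standardized module submatrix, oriented so the mean gene–eigengene
  correlation is positive; eigengene–trait Pearson correlations use a
  Bonferroni threshold of 0.05 / n_modules.

The information-theoretic arm discretizes each gene into
⌊√n_samples⌋ equal-frequency levels (stable rank tie-breaking), computes
plug-in empirical MI in nats, and applies DPI pruning with tolerance 0: in
every triangle the weakest edge is removed when strictly below the smaller
of the other two. Consensus networks intersect TOM edges (TOM ≥ 0.02, a
configurable export convention) with DPI-surviving MI edges; hubs are the
top 20 nodes by unweighted degree (ties by weighted TOM degree, then
lexical gene id), and hub networks add their first-degree neighbors.

## Enrichment and catalog preparation

Fisher's exact tests are two-sided by the probability-mass rule (the sum of
hypergeometric table probabilities ≤ the observed one), on a 2×2 table over
a declared background — for hub networks, all genes that entered network
construction. Zero-margin odds ratios are reported as undefined with a
Haldane-corrected OR ((a+½)(d+½))/((b+½)(c+½)) alongside. Catalog rows are
kept when the lead-variant p is strictly < 5×10⁻⁸ and the position falls
inside the named gene's [start, stop] (1-based inclusive, same chromosome);
a variant inside several genes keeps all of them. Orthologue mapping drops
unmapped genes (counted) and expands one-to-many mappings; trait curation
is user-supplied (raw → superseding trait), producing per-trait sets plus
their pooled union.

## PCA distances and outliers

PCA is computed on gene-centered, unscaled transformed values with samples
as observations and a deterministic sign convention (the largest-magnitude
loading of each component is positive). Centroids are per-method means of
(PC1, PC2); within-method distances are compared between methods with
Welch t-tests (robust to the unequal spreads that are the finding itself).
Methods with one sample are excluded with a note. Outlier flagging combines
an unmapped-read threshold (> 0.8) with a 3-robust-z rule (median/MAD per
group on PC1/PC2); exclusion is left to the caller.

## Reported problem sizes

The benchmark experiments run at: 1 000 genes (regulation recovery),
1 200 total (DE calibration), 400 genes × 40 samples (network recovery),
and 2 000 genes on the study layout with a 600-gene subsample for variance
partitioning (qualitative orderings) — sizes chosen so the whole
reproduction completes in well under a minute on one CPU while keeping the
Monte-Carlo error of each reported rate small relative to its acceptance
band.

## Known limitations

* The NB engine is intentionally simple: no fold-change shrinkage, no
  Cook's-style outlier handling, no multi-factor designs beyond an optional
  sex covariate in the generator.
* Exact scaling invariance of GLM coefficients under joint count/size-factor
  rescaling holds only in the Poisson limit; with quadratic NB variance the
  IRLS weights are scale-dependent (shifts ~10⁻² at α = 0.1, μ = 150).
* The static-cut module detector is deterministic but less adaptive than a
  dynamic hybrid tree cut; very unequal or nested block sizes may merge.
* MI estimates at n ≲ 20 samples are coarse (few discretization levels);
  DPI with tolerance 0 is aggressive on near-ties.
* The variance partition treats covariates as random intercepts; continuous
  covariates are out of scope.
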