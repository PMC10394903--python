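# Methods

## The deconvolution model

A bulk RNA-seq profile of a mixed sample is modeled as a proportion-weighted
sum of cell-type expression profiles.  For mixture *i* with bulk profile
*z<sub>i</sub>* and a reference matrix *X* whose column *x<sub>j</sub>* is the
expected expression of cell type *j*, the ordinary least squares baseline
solves

  min<sub>p</sub> Σ<sub>g</sub> ( z<sub>g,i</sub> − Σ<sub>j</sub> p<sub>ij</sub> x<sub>g,j</sub> )²

NNLS adds p ≥ 0; the robust baseline replaces the squared loss by the Huber
loss (tuning constant 1.345, IRLS to tolerance 1e-8).  Dampened weighted
least squares (DWLS) reweights genes by the inverse squared predicted
expression, w<sub>g</sub> = 1/(X p)<sub>g</sub>², so that rare cell types —
whose signal lives in lowly expressed genes — are not drowned out by highly
expressed genes; because raw inverse-square weights explode for near-zero
predictions, they are capped ("dampened") at a multiple of the smallest
weight.  The cap multiple is selected from {2⁰ … 2¹⁴} by minimizing the
across-subsample variance of weighted least-squares solutions on 20 seeded
half-gene subsamples (the subsample index sets are shared across candidate
multiples, making the comparison paired).  The solver then iterates:
recompute weights from the current proportions, solve the weighted NNLS
problem, renormalize onto the simplex, and average the new solution 1:4 with
the previous iterate — the stabilization used by the original dampened-WLS
procedure, which we adopted after observing oscillation with direct
stepping.  Iteration stops when the Euclidean step between successive
proportion vectors is ≤ 0.01 (read as an absolute bound; configurable) or
after 1000 iterations.  The cap multiple is chosen once per solve, from the
initial (NNLS) solution's weights.

All solvers report proportions under one convention: negative raw
coefficients are clamped to zero and the vector is renormalized to sum 1.
The raw solution is preserved on every result so the alternative convention
(no clamping) can also be evaluated.  The degenerate all-non-positive case
reports the uniform vector.

## Per-gene transformation into single-cell space (SQUID)

Bulk and droplet single-cell assays distort the same transcriptome
differently (capture efficiency, gene length effects, dropout), so a
cluster-mean reference X built from single-cell data is biased relative to
the bulk profile it must explain.  With *concurrent* profiles — the same
samples measured by both assays — that distortion is estimable per gene.
Writing ẑ<sub>g,i</sub> for the pseudobulk of gene g in sample i (the mean
expression over that sample's cells) and z<sub>g,i</sub> for its bulk value,
each gene with nonzero total expression in both assays gets a simple linear
regression across samples:

  min<sub>a,b</sub> Σ<sub>i</sub> ( ẑ<sub>g,i</sub> − (a<sub>g</sub> z<sub>g,i</sub> + b<sub>g</sub>) )²

solved in closed form (a = cov/var, b from the means; genes with zero bulk
variance fall back to the flat model a=0, b = mean pseudobulk).  Bulk
profiles are then mapped through z → a<sub>g</sub>z + b<sub>g</sub> and
deconvolved by DWLS against the raw-count cluster-mean reference, using all
genes nonzero in both the transformed column and the reference — no marker
selection.  A moment-matching variant rescales each gene to the pseudobulk
mean and standard deviation,
z → mean(ẑ<sub>g</sub>) + sd(ẑ<sub>g</sub>)/sd(z<sub>g</sub>) ·
(z − mean(z<sub>g</sub>)), and does not require concurrency; on default
synthetic data the two variants score within 0.02 RMSE of each other
(tested).

Evaluation uses leave-one-out cross-validation: each sample's composition is
predicted from a transform and reference fit on the remaining samples only.
The fold construction subsets the cell table before anything is computed, so
the held-out sample's single-cell data cannot leak into its own prediction;
a sentinel-gene test asserts this.

Design choices where the procedure was genuinely open:

* "Nonzero in both assays" is evaluated dataset-wide (gene totals) for
  fitting the transform and per-column for the deconvolution universe.
* Negative transformed values are kept; the solver's weights come from
  predicted reference expression, not from the bulk, so negatives are
  harmless to the weighting.
* The convergence norm is Euclidean and the 0.01 bound absolute.
* Single-sample datasets cannot support the per-gene regression (slope
  undefined); callers should use the moment-matching map there.

## Preprocessing

* **Cell QC** removes cells strictly below the 0.5% or strictly above the
  99.5% quantile of mitochondrial or ribosomal content (union over the two
  covariates; quantiles over all cells jointly).  Strict inequalities mean a
  constant covariate removes nothing and tail=0 is the identity.  Fractions
  are computed from gene-name prefixes (MT-, RPS/RPL; configurable) when
  not supplied.
* **Detectable genes** survive if, in at least one cluster, they are
  expressed (count > 0) in ≥ 10 cells or ≥ 1% of that cluster's cells — a
  logical OR of the two arms.
* **Normalization grid**: none, TPM (gene-length rate scaled to 1e6 per
  column), TMM (trimmed mean of M-values: 30% trim on M, 5% on A,
  precision-weighted mean, reference column by closest-to-mean upper
  quartile, factors normalized to unit geometric mean; validated against
  Bioconductor edgeR on a frozen fixture), and LogNormalize
  (log(1 + 1e4·count/colsum), natural log).
* **Cluster profiles** are arithmetic means of raw counts over each
  cluster's cells; the per-cluster cell counts ride along for weighting.
* **Markers** come from one-vs-rest two-sided Wilcoxon rank-sum tests on
  TMM-normalized data (asserted via the unit tag) with a log2(1.5)
  fold-change gate.  The fold change uses a pseudocount of 1 on TMM-scale
  means, and p-values are Benjamini–Hochberg adjusted at 0.05; the test and
  threshold are standard, the pseudocount and adjustment are this package's
  choices.  Clusters under 3 cells are skipped.
* **Cluster merging** iterates: compute pairwise Pearson correlations of
  cluster-mean profiles, greedily take non-overlapping pairs in descending
  correlation among those with r ≥ 0.95 (ties broken lexicographically),
  merge each pair by cell-count-weighted mean, and repeat until no pair
  qualifies.  Merging is expected on log-transformed, library-size
  normalized profiles; an auditable merge log (iteration, pair, r, new id)
  is returned.  The pass count is bounded by the initial cluster count − 1
  and total cell count is conserved.

## The synthetic concurrent-data generator

The generator emulates a six-type cell-mixture series with known truth:
three tumor-like types share most of the mass (one sample dominated ≥ 66%
by one type, one balanced sample, the rest Dirichlet), two immune-like
types jointly hold exactly 15% of every mixture, and a rare stem-like type
cycles through 0.5%/1%/2%.  Defaults: 6 samples, 2000 genes, 2000 cells per
sample, bulk depth 1e6.

Expression model (all synthetic assumptions of this module, not claims
about any real dataset): type mean profiles are log-normal (meanlog 0,
sdlog 1) with disjoint 5% marker blocks boosted ×8 per type.  Bulk counts
are Poisson around depth-scaled mixture expectations with mean-one
multiplicative log-normal noise (sdlog 0.1).  Cells are assigned to types
multinomially by the true proportions; per-cell counts are negative
binomial (dispersion 0.5) around type means distorted by a per-gene
log-normal capture factor (sdlog τ, default 0.5), per-gene dropout
thinning 1 − exp(−0.5 · pooled mean), and a mean-one per-cell size factor
(sdlog 0.3).  The gold standard is the realized cell fraction per sample.

Two modeling choices matter for what the tests prove.  First, the injected
platform bias is *per-gene and type-independent* (capture and dropout both
depend on the gene only, and single-cell depth scaling is one global
scalar), so each gene's pseudobulk is an exactly linear function of its
bulk expectation — the regime the per-gene transform provably corrects.
An optional type-dependent bias switch exists to probe the model's failure
mode.  Second, `expected_value_mode` emits exact expectations instead of
samples: one exact-mean cell per (sample, type) and the exact pseudobulk
attached explicitly.  On such data the transform-then-deconvolve estimate
recovers the design to numerical precision, while DWLS on untransformed
bulk is measurably biased at τ = 0.5 — both tested.

What the generator does **not** emulate: gene–gene correlation within a
type, batch and chemistry effects beyond a single multiplicative factor,
ambient RNA, doublets, type-dependent capture (off by default),
cryopreservation-style selective cell loss, or realistic gene lengths.
Passing tests therefore demonstrate correctness of the algorithms under a
clean, identifiable bias model, not performance on real tissues.

## Benchmarking

Estimates and gold standards are aligned by sample and cell-type id
(order-independent; unmatched types dropped with a logged count), flattened,
and compared by sample Pearson correlation and RMSE over all
(sample, type) pairs — 36 points for the canonical 6×6 design.  RMSE is
computed on the flattened matrix, and Pearson on untransformed proportions.
Zero-variance flattened vectors make the correlation undefined; it is
reported as missing with a reason while RMSE is still computed.  A utility
implements the Fisher z test for comparing two correlations.  The grid
runner crosses solvers with bulk/reference normalizations, records per-cell
failures without aborting, and accepts externally produced composition
tables so methods not implemented here can join the comparison.

## Problem sizes and numerical notes

The replicate study behind the SQUID-vs-DWLS comparison uses 20 seeded
datasets at generator defaults (6 samples × 2000 genes × 2000 cells,
τ = 0.5); the bias-monotonicity property test uses 8 seeds at 1000 genes ×
1200 cells per sample, sizes chosen to keep the full suite fast on a single
CPU.  The weight floor in DWLS is δ = 1e-12 × max predicted expression²;
the damping grid is 2⁰…2¹⁴; NNLS is Lawson–Hanson (deterministic).  All
randomness flows through explicit integer seeds, and replicate seeds are
small offsets of the run seed.

## Known limitations

* The per-gene linear correction cannot fix type-dependent distortions; the
  generator's type-dependent bias switch demonstrates this failure mode.
* TPM requires user-supplied gene lengths; no annotation retrieval.
* Gene identifiers are matched as exact strings; no symbol/Ensembl mapping.
* Clustering itself is out of scope: the pipeline consumes labels and
  offers only the correlation-based merging heuristic on top of them.
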