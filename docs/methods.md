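# Methods

## Problem setting

Given a compound with measured drug-induced gene-expression changes, rank a
panel of candidate proteins by how likely each is a target of the compound.
Supervision comes from a gold standard of known compound–protein
interactions; every unlisted pair of the compound × protein universe is
treated as a negative, so the task is ranking under extreme class imbalance
rather than calibrated classification.

## Expression processing

Inputs are per-instance (treatment/control) expression values that have
already been normalized upstream; array normalization itself is out of
scope. Processing has three steps:

1. **Instance selection.** One instance per compound within the chosen cell
   line: restrict to the cell line, take the highest treatment
   concentration, break ties by smaller batch ID, then smaller instance ID.
   Selection is idempotent and deterministic.
2. **log2 fold change**, treatment over control. Normalized intensities are
   positive; if a control entry is exactly zero (possible in degenerate
   synthetic input) a pseudocount of 1.0 is added to both channels.
3. **Probe collapse.** Arrays carry several probes per gene. Within each
   instance probes are ranked ascending by |log2 FC| (midranks for ties);
   for each gene the probe with the highest average rank across instances —
   the most responsive probe — is kept, its signed column copied verbatim.
   Representative ties break toward the smaller probe ID. Ranking by
   absolute change (rather than signed) is an interpretation: variability,
   not direction, is what distinguishes responsive probes, consistent with
   the finding below that |X| is the informative scoring scheme.

## Kernels

* **Compound expression similarity**: Pearson correlation between compound
  rows of the fold-change matrix. By default the correlation is computed on
  |X|: scoring-scheme comparison (see "Direct method") shows magnitude, not
  sign, carries target information, and compounds affecting the same target
  may regulate its signature in opposite directions. Zero-variance profiles
  get similarity 0 (with a warning) rather than an error, since constant
  rows arise in small synthetic runs; diagonals are forced to 1.
* **Protein expression similarity**: the same Pearson kernel applied to the
  columns of |X| at each protein's encoding gene. Proteins with no matching
  gene column are dropped with a warning.
* **Chemical similarity**: generalized Jaccard / real-valued Tanimoto,
  x·y / (‖x‖² + ‖y‖² − x·y), over nonnegative descriptor counts. Raw counts
  are used without column normalization; the min/max Jaccard variant is
  available behind a flag but is not the default.
* **Sequence similarity**: Smith–Waterman local alignment (BLOSUM62, gap
  open 10.0, gap extension 0.5; a length-L gap costs open + (L−1)·extend),
  cosine-normalized as SW(i,j)/√(SW(i,i)·SW(j,j)) so the diagonal is
  exactly 1. Alignment is delegated to Biopython's pairwise aligner; the
  test suite checks it against an independent dynamic-programming
  implementation.
* **Integrative kernels** are element-wise averages of the corresponding
  transcriptomic and chemogenomic kernels.

Pearson and Tanimoto kernels are positive semidefinite (up to roundoff);
the normalized Smith–Waterman kernel need not be. `make_psd` repairs
indefinite kernels by clipping negative eigenvalues to zero — clipping, not
diagonal shifting, to preserve the unit diagonal as closely as possible.
Training refuses kernels with eigenvalues below −1e−6.

## Pairwise kernel regression

The pair score is f(x′,y′) = Σᵢⱼ βᵢⱼ k_c(xᵢ,x′) k_p(yⱼ,y′). The weights
minimize squared loss with a ridge penalty over all n_x·n_y training pairs,
i.e. solve (K_c ⊗ K_p + λI) vec(β) = vec(Y). With eigendecompositions
K_c = USUᵀ and K_p = VTVᵀ the solution is β = U[(UᵀYV)/(sᵢtⱼ+λ)]Vᵀ —
algebraically identical to the dense solve (verified to 1e−8 in tests) at
the cost of two small eigendecompositions. Design choices the method leaves
open and how they are fixed here:

* **Loss/regularizer**: squared loss + ridge (kernel ridge regression on
  the Kronecker kernel), the standard reading of pairwise kernel
  regression and the source of its computational efficiency.
* **λ = 1.0 by default**, configurable; no tuning protocol is built in
  beyond passing a different value.
* **Labels are 0/1** (not ±1); only the ranking of scores matters
  downstream.
* **All pairs are used in training** — every non-positive pair of the
  training compounds × panel is a negative; no negative subsampling.

## Evaluation protocol

The candidate panel is the set of proteins appearing in the gold standard,
not the whole genome. Metrics are computed **per compound** over the panel
and averaged: AUC (midrank formula; 0.5 = random, 1 = perfect) and AUPR
(area under the precision–recall step curve with thresholds at distinct
scores; random baseline = positive fraction). Compounds with no positive,
or no negative, in the panel are excluded from every average and ratio.
Top-k ratios count compounds with ≥1 known target in their k top-scoring
proteins, score ties broken by ascending protein ID.

Cross-validation splits compounds (never proteins) into k=5 near-equal
random folds; each fold's compounds are scored by a model trained on the
rest, with the protein kernel computed once on the common panel.
Per-compound metrics are pooled across folds into a single report (fold
sizes differ by at most one, so pooling vs. averaging fold means is
immaterial).

Note that the AUPR step-curve estimator is biased upward for short vectors
with few positives (mean ≈0.09 for 5 positives in 100 at random); the
random-baseline property is therefore stated and tested at the
gold-standard-like composition (~6 positives in a 584-protein panel), where
the bias is below 0.01.

## Chemical-diversity benchmarks

Interaction databases are enriched in near-duplicate derivatives of common
lead scaffolds, which make compound-wise cross-validation optimistic.
Benchmark subsets retain one representative per chemical cluster:
complete-linkage hierarchical clustering on distance 1 − Tanimoto, cut at
height 1 − t, which guarantees every within-cluster pair has similarity
≥ t. Complete linkage is chosen precisely because it is the only common
linkage with that cut guarantee. The representative is the cluster member
with the most gold-standard targets (ties by ascending compound ID) — a
convention, since any member is defensible. At t = 1.0 every compound is
kept (singleton clusters by convention, so the full benchmark includes
exact duplicates). Thresholds are typically 0.4–1.0 in steps of 0.1; values
below 0.4 are accepted but degenerate (very few clusters survive).

## Synthetic data generator

The generator is the package's study-condition definition, not a test
fixture. Mechanism and defaults:

* **Scale**: 120 compounds × 30 proteins × 600 genes; each protein maps
  one-to-one to a distinct gene.
* **Signatures**: each protein perturbs 5% of genes. Downstream loadings
  have magnitude Uniform(0.6, 1.0) with random sign; the protein's own gene
  is fixed at loading 1.0, the maximum. `effect_size` (default 2.0) scales
  signatures against `noise_sd` (default 1.0), so it is exactly the z-score
  of the target's own gene. This regime makes the single-gene (direct)
  signal recoverable but modest, while the 30-gene aggregate footprint is
  strong — the qualitative regime in which supervised comparison of whole
  profiles clearly beats reading off single fold changes.
* **Targets**: 1 + Poisson(mean − 1) per compound (default mean 2), drawn
  uniformly without replacement; every compound has at least one target.
* **Expression**: row = effect_size × Σ (±signature of each target) +
  N(0, noise_sd), the sign flipped with probability ½ per compound–target
  (inhibitor vs activator). Flips make raw X uninformative while |X| keeps
  the signal — the construction behind the absolute-value result.
* **Descriptors** (64, nonnegative): each compound's vector interpolates
  between a per-primary-target center and an independent random vector,
  controlled by `structure_coherence` ∈ [0,1] (1 = tight target-determined
  clusters, 0 = structure says nothing about targets), plus small jitter,
  clipped at 0.
* **Sequences**: proteins are grouped into families of ~3; members derive
  from a uniform-random ancestor (length 120) by per-site mutation at rate
  0.2 to a uniformly random different residue.
* **Determinism**: one seed; independent substreams for signatures,
  targets, expression, descriptors and sequences.

What the generator does **not** emulate: real microarray noise (heavy
tails, intensity-dependent variance), batch effects, dose–response
structure, correlated off-target pharmacology, realistic descriptor
distributions, or homology between targets and their signatures. Passing
tests show the methods recover planted structure of the assumed form; they
are not evidence about accuracy on real compendium data.

## Numerical and procedural conventions

* Matrices serialize at 17 significant digits; loading uses numpy's float
  parser so write∘read is bit-exact.
* Deterministic tie-breaks throughout: probe collapse (smaller probe ID),
  Top-k (ascending protein ID), cluster representatives (most targets, then
  smaller compound ID), prediction files (descending score, then compound,
  protein).
* AUC uses midranks, so tied scores contribute ½ per positive–negative
  pair.
* Stochastic pattern checks in the acceptance tests average over five
  replicate datasets (fixed seeds) because single-dataset mean AUC varies
  by ±0.05 under the null.
* With a 30-protein panel the Top50 ratio saturates at 1 for every method;
  method comparisons on Top50 are only meaningful with panels larger
  than 50.

## Known limitations

* The transcriptomic approach requires the compound to have been profiled;
  it cannot score unprofiled compounds.
* λ is not tuned; performance comparisons at the default may understate any
  method's ceiling.
* Proteins sharing an encoding gene column are indistinguishable to the
  direct method and to the transcriptomic protein kernel.
* The evaluation excludes compounds with no panel target, so reported means
  say nothing about compounds outside the gold standard.
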