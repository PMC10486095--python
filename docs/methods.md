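# Methods

## Model

A gene's binarized epigenomic data in one cell type is a T x E matrix `X`
(200-bp bins along the flank-extended gene, ordered 5'→3'; one column per
mark).  `X` is modeled as generated by exactly one of `M` mixture components.
Component `m` is a fully connected hidden Markov model with `S` states:

- **Initial probabilities** `τ_{m,s}`: the probability that a random gene
  starts in state `s` of component `m`.  These sum to 1 over all `M·S`
  states, and `π_m = Σ_s τ_{m,s}` is the component prior.
- **Transitions** `α_{ms,ms'}`: within a component only; transitions between
  states of different components have probability exactly 0.  Each state also
  has an exit probability (leaving the gene).
- **Emissions** `β_{m,s,e}`: the probability of each mark being present,
  combined across marks as a product of independent Bernoullis.

Disallowing cross-component transitions makes the component posterior
`P(m | X) = Σ_s p(H_{m,s} | X)` constant along the gene, so a single
per-gene label is well defined; the code asserts this constancy (tolerance
1e-9) instead of assuming it, because a violation indicates a corrupted
transition mask.

To train across cell types, the same gene in different cell types is treated
as additional genes ("concatenated" training): one common model, cell
type-specific assignments.

## Encoding as a single HMM

The mixture is trained and decoded as one HMM with `M·S + 1` states.  Genes
in a (cell type, chromosome) file are concatenated with a single *dummy
position* between them (and at both file ends).  A dummy position has all
real marks absent and a synthetic *dummy mark* present; the extra *dummy
state* is the only state that emits the dummy mark (and never emits real
marks), so the chain is forced through it between genes.  Transitions out of
the dummy state are the flattened `τ`; the dummy column of the transition
matrix holds the exit probabilities; all cross-component entries (and
dummy→dummy) are structural zeros.  Parameters that are exactly 0 or 1 when
training starts are held fixed throughout, which preserves this structure
under EM.

This encoding keeps the file count at (cell types) x (chromosomes) — 2,921
files for a 127-epigenome, 23-chromosome panel — instead of one file per
(gene, cell type).

## Input conventions

- Coordinates are 0-based half-open internally; GTF input is converted on
  read.
- Genomic start and end are rounded *outward* to bin-width multiples (this
  realizes rounding the TSS in the 5' direction and the TES in the 3'
  direction for both strands), then a 2,000-bp flank is added on each side.
- Negative-strand genes are row-reversed after extraction so every
  observation runs 5'→3'; mark columns are never reordered.
- Flanks are clamped at chromosome boundaries (the convention here; genes
  are never dropped for being near an edge).  Overlapping genes are extracted
  independently, repeating shared rows.
- Chromosomes default to autosomes 1–22 plus X; the list is configurable.

## Numerical scheme

Forward variables are rescaled at each position by the sum of the forward
variables; backward variables — independently — by the sum of the backward
variables.  Rescaling the backward pass by the *forward* sums (the textbook
single-HMM scheme) overflows here, because one component can dominate the
forward recursion while another dominates the backward recursion.  After
scaling, backward variables below 1e-300 are floored to 1e-300; forward
variables likewise, *except* where the emission product is exactly 0, which
is kept at 0.  The floor is applied after scaling (the order is a
documented choice; before/after differ only in which of two representable
tiny numbers survives).  The sequence log-likelihood is the summed log of the
forward scale factors.  An observation sequence with zero probability raises
an explicit impossible-sequence error rather than dividing by zero.

State posteriors are the per-position normalized products of the scaled
forward and backward variables; pairwise transition expectations are
normalized per position pair, which sidesteps any bookkeeping between the two
independent scale sequences.

## Training

Baum-Welch EM for a fixed number of iterations (default 200) with no
convergence threshold.  Each iteration draws a fresh uniform subsample of
input files (default 100) — the recorded per-iteration log-likelihood is
therefore not comparable across iterations unless subsampling covers all
files, and it is never used for early stopping.  The M-step re-estimates `τ`
from dummy-row transition expectations, within-component transitions and
exits from pairwise expectations, and emissions from posterior-weighted mark
counts; a state receiving zero expected mass keeps its emissions for that
iteration (logged).

Initialization: `τ` is one Dirichlet(1) draw over all `M·S` states; each
within-component transition row is a Dirichlet(1) draw scaled to 0.95 with
the remaining 0.05 on the dummy exit (the 0.05 exit mass is exposed as
`exit_mass`); emissions are empirical mark frequencies after assigning each
gene uniformly to a component and each bin uniformly to a state, with a
global-frequency fallback for states that received no bins (a fallback of
0.5 would make the first E-step needlessly flat).

**Implementation note.**  The E-step splits each concatenated file at its
dummy rows into per-gene segments (each re-bracketed by dummy rows) and runs
the scaled recursions batched over equal-length groups.  Because a dummy
position deterministically resets the chain — all scaled forward mass sits in
the dummy state there — the per-segment quantities are algebraically
identical to the full-sequence ones, and accumulated expectations are plain
sums, so results do not depend on the grouping.  The public
`forward_backward` runs the faithful single-sequence recursion and is
cross-checked against exhaustive path enumeration and a log-space reference
in the test suite.

**Restarts.**  Mixture EM is multimodal; a single random start can merge two
true components (observed on the recovery fixture as a clearly lower dataset
log-likelihood).  `em_train_restarts` runs a few short starts (default 3 x 10
iterations), keeps the one with the best dataset log-likelihood, and trains
it fully.  Selection uses only the data likelihood.

## Assignment and baselines

Genes are hard-assigned to the argmax-posterior component; ties break to the
lowest component index (documented, tested).  Per-position state posteriors
can be emitted, with the caveat that states are not comparable across
components.

- **TSS baseline**: one observation row per gene (the bin containing the
  TSS; for negative-strand genes the TSS coordinate is `end − 1` under the
  half-open convention), trained with `S = 1`.
- **Gene-average baseline**: the main pipeline with `S = 1` — no separate
  code path.
- **Collapsed baseline**: from the trained multi-state model, each
  component's emissions are averaged weighted by `π_{m,s}` — the fraction of
  bins hard-assigned to state `s` among component-`m` bins, aggregated over
  all cell types and genes (per-bin states are the maximum-posterior state
  within the gene's assigned component).  The collapsed initial probability
  is the component prior; with `x_m` assigned bins and `n_m` assigned genes,
  the self-transition is `(x_m − n_m)/x_m` and the exit `n_m/x_m`.  It is
  never trained further.

## Evaluation statistics

All consume hard assignment matrices (genes x cell types).  Default
thresholds: pseudocount 0.1 before log10-transforming RPKM; expressed means
RPKM ≥ 1; highly expressed means RPKM > 100; constrained means pLI ≥ 0.9;
enrichment significance at adjusted p < 0.01.

- **Expression prediction**: leave-one-chromosome-out; per-annotation
  training-gene median transformed expression predicts held-out genes.
  AUROC is the rank-based (Mann-Whitney) estimator with tie correction; MSE
  and Pearson r are pooled over folds per cell type.  Method comparisons use
  a one-sided binomial test on per-cell-type wins, with ties counted against
  the method being tested (the conservative reading).
- **Mutual information with gene length**: log10 length discretized into
  0.05-wide bins; MI reported in bits.
- **Confusion / contingency**: row-stochastic conditionals
  P(label in c' | label in c) accumulated over genes and both orientations of
  replicate pairs (confusion) or all non-replicate unordered pairs
  (contingency); cell-type specificity of annotation i is
  `1 − contingency_ii / confusion_ii`.
- **Co-assignment enrichment**: log2 of the symmetrized, sum-normalized
  observed co-assignment matrix over non-replicate pairs divided by the outer
  product of empirical priors; never-observed combinations are reported
  missing.
- **Gene-set enrichment**: upper-tail hypergeometric per cell type with
  (universe, set size, annotation size, overlap); fold is the mean over cell
  types of P(annotation | set) divided by the annotation prior (so a set
  equal to the universe has fold exactly 1); summary p is the median across
  cell types.  Bonferroni correction takes a caller-supplied test count,
  because the correction universe differs between analyses.  The random-split
  comparison restricts to the minimal expression-ordered prefix of
  annotations covering ≥ 75% of tested genes and compares the count of
  significant (set, group) combinations against 100 size-matched random
  splits.
- **Expression permutation test**: statistic is the mean within-annotation
  variance of per-(annotation, cell type) median expression; the null
  permutes the pooled medians preserving group sizes; p is the fraction of
  permutations with statistic ≤ observed (non-strict, so a fully degenerate
  input is not significant), with p below 1/n_perm flagged as such.
- **Expression-change matrix**: mean log2 expression ratio per
  (annotation in cell type i, annotation in cell type j) bin over ordered
  pairs of distinct cell types.
- **pLI analysis**: overall high-pLI proportion per annotation; 15 log10
  length bins on [3, 6] (genes outside discarded) with a length-density-
  normalized proportion; 30 expression bins on [−1, 2] with per-bin high-pLI
  proportion and mean pLI; Spearman correlation of expression and pLI per
  cell type.
- **Hyperparameter metrics**: replicate concordance ("reproducibility") and
  the mean closest-state Manhattan distance between within-component emission
  vectors (undefined for S = 1).
- **Assignment visualization**: pairwise gene distance
  `1 − mean_c I(label_i = label_j)` on up to 2,000 sampled genes, clustered
  with UPGMA linkage and optimal leaf ordering (scipy).

## Synthetic data

The generator exists so every stage is testable against a known truth with
no external data.

- `sample_ground_truth_model` anchors each component at a random binary mark
  pattern; states flip ~25% of the anchor marks and add small jitter, then
  candidates are rejection-sampled until component mean-emission profiles are
  ≥ `separation` apart in L1 (default 2.0) and states within a component are
  ≥ 1.0 apart — so both components *and* states are identifiable.  Component
  priors are Dirichlet(5) (no starved components at small n); transition rows
  mix a 0.6 self-weight with a Dirichlet(1) draw, giving mark domains some
  persistence.
- `simulate_dataset` lays genes with log-normal lengths (default median
  30 kb, the realistic scale; the small CI fixture uses median 8 kb, clipped
  to 2–60 kb) on synthetic chromosomes with non-overlapping flanks and random
  strands, draws a component per (gene, cell type) from the prior (replicate
  cell types copy their partner's label with configurable concordance),
  simulates the component HMM over the extended region, applies symmetric
  per-bin flip noise (default 2%), and writes standard input files.
- `simulate_covariates` draws RPKM log-normally around per-component means
  (defaults spread over log10 RPKM [−1, 2]), pLI from per-component high-pLI
  rates, and planted gene sets that over-sample a target component at a given
  odds ratio.

One integer seed drives everything through `numpy.random.SeedSequence`
spawning (model, dataset, covariates), so fixtures are bit-reproducible.

What the generator does *not* emulate: mark-specific autocorrelation beyond
what the HMM induces, imputation artifacts, copy-number or mappability
structure, non-stationarity along real genes, or realistic gene clustering.
Passing recovery tests therefore demonstrates correctness of the inference
machinery under the model's own assumptions, not performance on real
epigenomes.

## Problem sizes and defaults

The verification battery (tests and `scripts/acceptance.py`) uses:
M=4 components, S=2 states, E=6 marks, separation 2.0, flip noise 0.02;
200 genes x 4 cell types for unit-level fixtures and 500 genes x 4 cell
types for the recovery gate; EM with 3 restarts x 20 iterations plus 130
further iterations on the best start, subsample 100 files (= all files at
this scale); a 60-gene
x 2-cell-type full-batch fixture for the monotonicity check; and a single
50,000-bin gene with emissions clipped to [0.001, 0.999] for the stability
regression.  The analysis-scale defaults surfaced by the CLI are bin width
200 bp, flank 2,000 bp, M=12, S=3, 200 iterations, 100-file subsamples.

## Known limitations

- Bernoulli-product emissions only; no Gaussian or negative-binomial path.
- No signal binarization from raw coverage — pre-binarized tracks are the
  input, as in the upstream position-level tooling.
- Evaluation consumes hard assignments; soft/fractional downstream analyses
  are out of scope.
- EM recovers parameters up to a global permutation of components (and of
  states within components); comparisons to a ground truth must align labels
  first, as the tests do.
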