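# Methods

## Model

AMVML treats miRNA–disease association prediction as graph-regularized
multi-label learning over two entity spaces at once.  Its inputs are a binary
association matrix `Y` (q diseases × p miRNAs) and one or more square
similarity views per space.  Rather than averaging the views, it learns a
*consensus affinity graph* per space — a matrix whose every row lies on the
probability simplex, so row i is a distribution over that entity's neighbors
— and it learns how much to trust each view at the same time.  The objective
(README) balances three forces:

1. **View fitting.**  Each learned graph should stay close (Frobenius) to
   every view, with per-view weights `w^(v) = 1/(2‖S − A^(v)‖_F)` that are
   themselves re-estimated from the current consensus.  This inverse-distance
   rule is the fixed point of minimizing a square-root-of-sum-of-squares
   surrogate; its practical effect is that unreliable views are discounted
   without any hand-set weights.
2. **Label consistency.**  The quadratic forms `Tr(Fᵀ L_SD F)` and
   `Tr(F L_SM Fᵀ)` penalize score profiles that differ between entities the
   learned graphs consider similar; equivalently the disease-graph term is
   `½ Σ_ij SD_ij ‖F_i − F_j‖²` over rows of F, and the miRNA-graph term the
   same over columns.
3. **Label fitting.**  `‖F − Y‖_F²` anchors the scores to the known
   associations.

The trade-offs α and β default to 1e-4 (best cross-validated setting); at
this scale F stays numerically close to Y and the *ranking* of the zero
entries — which is all that matters for prediction — is driven by the graph
propagation terms.

## Optimization

Alternating minimization with exact coordinate updates:

* **SD, SM rows.**  With everything else fixed, row i of SD solves
  `min ‖SD_i − (Σ_v w_v AD_i^(v) − (α/2) z_i)/Σ_v w_v‖²` on the simplex,
  where `z_ij = ‖F_i − F_j‖²`.  We use the exact O(k log k) sorting-based
  Euclidean projection (tested against a KKT-enumeration QP oracle) rather
  than an iterative approximation.  The miRNA problem is the transpose
  (z over columns of F).
* **F.**  The first-order condition of the objective in F is the Sylvester
  equation `(2α L_SD + I) F + F (2β L_SM) = Y`, solved with the
  Bartels–Stewart algorithm (`scipy.linalg.solve_sylvester`).  Note the
  factor 2: the objective carries `2α`/`2β` on its trace terms, and
  differentiating a trace quadratic doubles the coefficient again while the
  label-fitting term contributes `2(F − Y)`; dividing by two gives the
  equation above.  The generic solver routine `update_F(SD, SM, Y, a, b)`
  solves `(a L_SD + I) F + F (b L_SM) = Y` for arbitrary non-negative a, b,
  and the fitting loop calls it with `a = 2α, b = 2β` so that the F-step is
  the exact subproblem minimizer — this is what makes the monotone-descent
  guarantee below hold.  `a = b = 0` short-circuits to `F = Y` exactly.
* **Weights.**  After the inner loop converges, weights are recomputed from
  the inverse distances, with an ε = 1e-10 guard against a view coinciding
  with the consensus.

Because every inner step is an exact minimizer of a strictly convex
subproblem, the objective is non-increasing within each inner loop; the test
suite asserts this to 1e-9 slack on 50 seeded instances.  Across an outer
weight update the objective value jumps (the weights rescale two of its
terms), so the trace is recorded as one block per outer iteration.

Stopping rules: inner loop when the relative objective change falls below
1e-6 (cap 50), outer loop when the largest relative weight change falls
below 1e-4 (cap 10).  In practice the inner loops converge in 2–3 iterations
and 3–4 outer iterations suffice.  The solver is fully deterministic; all
arithmetic is double precision, and any non-finite iterate aborts with a
diagnostic rather than propagating NaNs.

A `normalized_laplacian` switch replaces `L` by `D^-1/2 L D^-1/2` in the
F-step and the objective.  The closed-form SD/SM row update is derived from
the unnormalized expansion, so with the switch on the updates are no longer
exact subproblem minimizers and the descent guarantee applies only to the
default (unnormalized) flavor.

## Similarity constructions

* **Disease semantic similarity.**  Each disease's MeSH ancestry is a DAG;
  the disease contributes 1 to itself and each ancestor contributes
  `max(0.5 · contribution(child))` over its children in the DAG, i.e. a 0.5
  decay per level along the best downward path.  Pairwise similarity is the
  summed contribution of shared nodes (from both sides) over the two total
  contributions.  Diseases without a DAG get zero off-diagonal similarity;
  the row stays valid and the choice is explicit rather than imputed.
* **miRNA sequence similarity.**  Global end-to-end pairwise alignment of
  mature sequences (match +1, mismatch −1, affine gaps with opening penalty
  5 and extension penalty 2).  By default the first gap position pays
  opening + extension (total 7), matching the convention of the Biostrings
  `pairwiseAlignment` function; a flag selects the other convention (first
  position pays only the opening).  Raw scores over *all* pairs — including
  self-alignments, so the diagonal attains the maximum — are min–max mapped
  to [0, 1].  T is normalized to U; ambiguous nucleotides are rejected
  rather than guessed.
* **miRNA functional similarity.**  Best-match averaging of disease semantic
  similarities between the two miRNAs' known disease sets, divided by the
  total set size.  The measure is undefined for a miRNA with no known
  disease; such rows/columns are set to 0 with a unit diagonal, and users
  are expected to supply additional label-independent views (e.g. a
  precomputed GO-based semantic view) for such miRNAs.
* **Interaction-profile (GIP) kernel.**  RBF kernel on rows (diseases) or
  columns (miRNAs) of Y with bandwidth `β = β′ / mean(‖profile‖²)`; the
  prior β′ defaults to 1, the standard choice in the GIP literature.

## Validation protocols

All schemes accept views either as fixed matrices or as *builders* that are
re-invoked on every masked training matrix.  Label-derived views (GIP
kernels, functional similarity) must be passed as builders so that masking a
test association also removes its influence on the views — the leakage guard
is asserted by a test that plants a single association and checks it
disappears from fold-time kernels.

* **Global LOOCV** masks one positive at a time and ranks it against all
  pairs unobserved in the full matrix; the global AUC is the mean exceedance
  of held-out positives over the candidate score distribution.
* **k-fold CV** (default 5 folds × 10 repeats) partitions positives
  per-repeat with a deterministically derived per-repeat seed and reports
  mean ± sd of fold AUCs.
* **LODOCV** blanks one disease's entire row and scores its recovery,
  yielding one AUC per disease with ≥1 positive; paired AUC vectors of two
  methods are compared with a two-sided Wilcoxon signed-rank test.
* **Top-N temporal validation** fits on an older snapshot and counts
  per-disease top-N candidates confirmed by a newer snapshot (a global
  single-ranking mode is also provided).

## Synthetic benchmark

`make_block_instance` draws a block-structured bipartite world: diseases in
3 and miRNAs in 4 contiguous latent groups (default 60 × 80), matched group
pairs with propensity 0.45 (0.9 scaled by overall density 0.5) and unmatched
pairs 0.025, and Y sampled Bernoulli.  Similarity views are convex mixtures
`(1−λ)·block-affinity + λ·noise` with symmetric uniform noise; the defaults
generate one faithful view (λ = 0.2) and one pure-noise view (λ = 1.0) per
space, the setting under which self-weighted fusion should — and, in the
tests, does — rank view quality correctly.  `sparsify_snapshot` thins
positives independently to emulate an older database release.  All
generators are pure functions of their seeds.

What the generator does *not* emulate: real MeSH DAG topology, sequence
evolution, the heavy-tailed degree distribution of curated catalogues, and
ascertainment bias (well-studied diseases accumulate associations faster).
Passing tests therefore demonstrate correctness and the model's headline
mechanisms (descent, self-weighting, recovery of planted structure), not
clinical-scale accuracy on curated data.

## Problem sizes and numerical choices

The test suite and the acceptance script run at 60 × 80 (solver properties,
self-weighting, k-fold, LODOCV), 20 × 25 (global LOOCV, which refits once
per positive) and 12 × 15 (protocol oracles), sizes chosen so the whole
suite completes in well under a minute while every property remains
non-trivial.  Oracle comparisons use 1e-8 tolerances; descent is asserted to
1e-9; simplex rows are checked to 1e-8.  Ties in rankings are broken stably
(by index) and credited 0.5 in AUCs.

## Known limitations

* The strict-descent guarantee covers the inner loops; the outer
  weight-update step is a heuristic fixed-point iteration and its objective
  is not monotone across outer boundaries (by design).
* At α = β = 1e-4 the learned simplex rows are sparse (~10–12 active
  neighbors at the default scale).  This is the intended "adaptive
  neighbors" behavior, but it discards graded similarity information, and on
  easy block-structured instances a dense similarity-vote baseline is
  nearly as accurate as the full model; the model's mean advantage there is
  real but small.
* Functional similarity is quadratic in p with a Python inner loop; fine up
  to a few hundred miRNAs, not tuned for thousands.
* The miRNA GO-semantic view is consumed as a precomputed matrix only; this
  package does not compute GO term similarities.
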