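# Methods

## Model and procedure

`tensorsel` treats an omics experiment with two sample axes — replicates
(or subjects) and ordered conditions (stages, tissues, time points) — as a
three-mode tensor `x[i, j, k]` of feature *i*, replicate *j*, condition
*k*, and extracts differential features unsupervised, in five steps:

1. **HOSVD.** Each mode-*m* unfolding is decomposed by SVD; the left
   singular vectors become the mode-*m* factor, and the core
   `G = x ×₁ U₁ᵀ ×₂ U₂ᵀ ×₃ U₃ᵀ` couples one component per mode. The
   decomposition is *economy*: mode *m* keeps `min(dim_m, Π other dims)`
   columns, which spans the same subspace as a full square factor (the
   discarded columns pair with an identically-zero core block). No
   iterative refinement (HOOI/ALS) is applied: the interpretation relies
   on factors being exactly the unfolding singular vectors.
2. **Replicate component.** Replicates are exchangeable, so the relevant
   mode-2 component should be constant across *j*. Constancy is scored as
   `|mean| / (SD + 1e-12)`; the argmax wins.
3. **Condition component.** The condition axis is ordinal, so the relevant
   mode-3 component should vary monotonically with the level order.
   Monotonicity is scored as `|Spearman ρ|` against the level ranks — with
   one guard: rank correlation is blind to amplitude, and in exact
   low-noise settings a nearly-flat component can carry an epsilon-sized
   leaked trend with a perfect Spearman score. Components whose relative
   variation (SD over RMS) is below 0.1 are therefore scored 0, extending
   the natural "constant ⇒ no dependence on k" convention; 0.1 separates
   flat-with-jitter columns (ratio ≪ 0.1) from genuinely trending
   unit-norm columns (ratio ≈ 1) by an order of magnitude on both sides.
4. **Feature component.** `l1 = argmax |G(l1, l2, l3)|` for the chosen
   `(l2, l3)` — the feature direction that contributes most to the
   selected sample pattern. Ties break to the smallest index.
5. **Selection.** The entries of `u_{l1}` are tested against the
   SD-optimized Gaussian null (below), BH-adjusted, and thresholded at
   adjusted P < 0.01.

Both sample components can be overridden explicitly; the score tables for
every candidate are logged and returned, so the automatic choice replaces
an interactive inspection without hiding the evidence.

### SD-optimized Gaussian null

Under the null a feature's score `u_i` is N(0, σ²) and
`P_i = Pr[χ²(1) > (u_i/σ)²]` (the two-sided normal tail). σ estimated
naively from all scores is inflated by the true signal; instead σ is
chosen so the *bulk* of the P-values looks uniform: `1 − P_i` is histogrammed
into B = 100 equal bins on [0, 1], the top 10% of bins (nearest 1, where
large-|u| signal concentrates) are excluded, and σ minimizes the
**coefficient of variation** (SD / mean) of the remaining bin counts.

The CV — not the raw SD — of the counts is essential: the raw SD has a
degenerate global minimum as σ → 0, where every score is pushed into the
excluded tail, the kept bins empty out, and their SD vanishes. Dividing by
the mean kept count blows that configuration up to +∞ while leaving the
minimizer under uniform P unchanged.

The search runs over `[0.01, 10] × sample SD` on a 64-point geometric grid
followed by bounded scalar refinement (relative tolerance 1e-4). Because
the bracket is relative to the sample SD and the objective depends only on
u/σ, the estimate is exactly scale-equivariant, which in turn makes the
final selection invariant under global rescaling of the input.

BH adjustment is the standard step-up `min_{j≥i} p_(j)·m/j` capped at 1,
implemented vectorized (with a floor at the raw P to absorb the 1-ulp
rounding of `(p·m)/m`).

### Multiomics route

K layers `x_k ∈ R^{N_k×M}` sharing M samples are contracted to a Gram
tensor `x[j, j', k] = Σ_i x_k[i,j] x_k[i,j']` (M×M×K) before
decomposition — the point is memory: nothing larger than
`max(M²K, max_k N_k·M)` entries is ever materialized, while the sample-side
eigenstructure is preserved exactly (for K = 1 the Gram eigenvectors are
the right singular vectors of the layer, so the route is equivalent to a
direct decomposition; a test verifies this). Feature rows are mean-centered
per layer first (default, configurable): uncentered Grams are dominated by
mean structure rather than covariation. The mode-1 component most
associated with the sample labels (|Spearman| for ordinal labels, absolute
point-biserial for two classes) is back-projected into each layer,
`u_{l1 i_k} = Σ_j u_{l1 j} x_k[i_k, j]`, and each layer's scores pass
through the null independently. σ is optimized **per layer**: projected
scores scale with layer size and spectrum, so a single shared σ would make
selection depend on which layers happen to be co-analyzed.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `threshold` | 0.01 | BH-adjusted P cutoff for selection |
| `bins` | 100 | histogram bins for the σ objective |
| `tail_fraction` | 0.1 | fraction of bins (nearest 1) excluded as signal tail |
| `sigma_bracket` | (0.01, 10) | σ search range as multiples of the sample SD |
| `preprocess` | none | optional `log1p` or per-feature z-score before HOSVD |
| `center` (multiomics) | True | per-feature centering before the Gram step |

The tail fraction trades robustness for efficiency: it must exceed the
true signal fraction of features for σ to stay uncalibrated by signal
(10% covers the planted 10% in the default simulations; raise it for
denser signal).

## Conventions

* Unfolding places mode *m* on rows; among the remaining modes the
  lower-numbered one varies fastest along columns. `fold ∘ unfold` is the
  bit-exact identity.
* Singular vectors have arbitrary sign; each factor column is flipped so
  its largest-|entry| element is positive, and the core absorbs the flip.
  Component indices `l1, l2, l3` are 1-based in all user-facing output.
* Equal singular values keep the decomposition's stable order. On the
  feature mode, when `N > 10·(M·K)`, the factor is computed from the
  eigendecomposition of the small-side Gramian (mathematically identical,
  cheaper); zero singular values are completed to an orthonormal basis
  deterministically from coordinate vectors.

## Synthetic data

The generator produces the structure the method assumes, with ground
truth. Tensor path (defaults: 1,000 features × 9 replicates × 4
conditions, 100 planted, effect 3.0, noise SD 1.0):
`x[i,j,k] = baseline_i + planted_i · effect · (k − (K−1)/2) + N(0, noise²)`,
with per-feature baselines N(6, 2²) emulating log-scale expression levels
and the trend identical across replicates. Multiomics path (defaults:
layers of 500/300/200 features × 60 samples, 4 ordered label levels, 10%
planted per layer): planted features load on one standardized label-aligned
sample factor with amplitude `effect · noise`.

What the generator does **not** emulate: count-distribution mean–variance
coupling, library-size differences, batch effects, feature–feature
correlation beyond the planted factor, or missing data. Passing tests
therefore demonstrate correctness of the algorithm under its own Gaussian
assumptions, not performance on raw sequencing counts (a log-normal option
exists for off-assumption smoke testing). Real count data should be
transformed/normalized upstream; the pipeline consumes the tensor as
given.

## Numerical choices and degenerate inputs

* Full-economy reconstruction is exact to 1e-10 relative Frobenius error;
  factor orthonormality to 1e-10; core all-orthogonality to 1e-8 (all
  verified on random tensors at every run of the acceptance script).
* All-zero tensors decompose without error (zero core, identity-completed
  factors). All-zero or constant score vectors are rejected by the σ
  optimizer with an explicit error; a single zero score yields P = 1.
* A balanced replicate×condition grid is required when assembling tensors
  from matrices; gaps and duplicates are reported, never imputed.
* The σ objective is piecewise constant (integer bin counts), so the
  bounded refinement converges to a point inside a flat region; the
  64-point grid makes the result deterministic and independent of
  optimizer internals to ~1e-4 relative.

## Known limitations

* Only one `(l1, l2, l3)` triple is selected per run; signals split across
  several feature components need repeated runs with overrides.
* The constancy/monotonicity statistics are simple summaries; heavily
  tied or very short condition axes (K = 2) make the Spearman score coarse.
* The near-constant gate (relative variation < 0.1) could in principle
  suppress a true trend riding on a large constant offset within one
  component; such components are rare because the leading constant
  direction is captured separately, but the gate is a fixed heuristic.
* The Gaussian null is an approximation for scores projected from heavy-
  tailed data; the BH threshold then controls FDR only approximately.
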