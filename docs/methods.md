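# Methods

## Model

Multiple co-inertia analysis treats N sample-by-feature blocks X₁, …, X_N
over the same n samples as views of one underlying sample configuration.
With X = [X₁|…|X_N] the global matrix and, for order j, the deflated
matrices X^(j) (X^(1) = original data), each order solves

    max  Σₖ cov²(X_k^(j) a⃗_k^(j), X^(j) a⃗^(j))

subject to unit-norm block loadings a⃗_k, a unit-norm block-weight vector
w⃗^(j), and the global score f⃗^(j) = Σₖ w_k^(j) f⃗_k^(j) built from the block
scores f⃗_k = X_k a⃗_k. The covariance is implemented as a plain inner
product: a 1/(n−1) factor would rescale every eigenvalue by the same
constant and cancels in all scree proportions, contributions, and cosines,
so the choice only fixes the reported scale.

The two classical variants differ only in the deflation that links orders:

* **block-loading deflation (MCIA)** — X_k ← X_k(I − a⃗_k a⃗_kᵀ). Block
  loadings become orthonormal within each block across orders; loadings
  remain combinations of the original features, which is what makes
  out-of-sample projection exact.
* **global-score deflation (CPCA)** — X_k ← (I − u⃗u⃗ᵀ)X_k with u⃗ = f⃗/‖f⃗‖.
  Global scores become orthogonal across orders.

## Solver

Each order runs the extended NIPALS fixed point: from a score direction u⃗,
(i) a⃗_k ← X_kᵀu⃗/‖X_kᵀu⃗‖, (ii) f⃗_k ← X_k a⃗_k, (iii) w_k ← f⃗_kᵀu⃗ then
normalize w⃗, (iv) f⃗ ← Σ w_k f⃗_k, u⃗ ← f⃗/‖f⃗‖. Substituting (i)–(iii) into
(iv) gives u⃗_new ∝ X Xᵀ u⃗: the iteration is exactly a power method on the
global cross-product, which yields monotonic convergence of the objective
u⃗ᵀX Xᵀu⃗ and identifies the fixed point with the dominant eigenvector. The
per-order eigenvalue is λ_j = Σₖ (f⃗_kᵀu⃗)², the objective value at the
optimum; the order-1 value is therefore the *global* maximum of the
objective, a fact the test suite exploits with a grid-search lower bound.

Numerical choices:

* **Initialization** — u⃗₀ is the largest-norm column of the current global
  matrix, normalized: deterministic, cheap, and never the zero vector. The
  limit of a power iteration does not depend on the start except on a
  measure-zero set.
* **Convergence** — ‖u⃗_new − u⃗_old‖₂ < tol after sign alignment, default
  tol = 1e-12, at most 1000 iterations per order; hitting the cap sets a
  `converged=False` flag rather than raising, so large runs always return.
* **Sign convention** — each a⃗_k is oriented so its largest-magnitude entry
  is positive (f⃗_k and w_k flip with it, leaving f⃗ invariant), then f⃗ is
  oriented the same way by flipping w⃗; eigen-equivalence is only defined up
  to these signs.
* **Dead blocks** — if ‖X_kᵀu⃗‖ falls below 1e-13 of the block's Frobenius
  norm (a fully deflated block), a⃗_k and f⃗_k are zeroed and the block drops
  out of the weight normalization for that order; it cannot poison later
  orders.
* **Rank exhaustion** — the requested R is capped at min(n, p); if variance
  runs out at some order (all blocks numerically zero), remaining orders
  are recorded with λ = 0 and zero vectors and a warning is attached to the
  result, keeping eigenvalue vectors a fixed length R.
* **Zero-variance columns** — standardization forces their scale to 1
  (the centered column is all-zero anyway), keeping feature indices stable
  for loadings and prediction.

## Preprocessing

Column methods: `none`, `center` (subtract the column mean), `standardize`
(center and divide by the sample standard deviation, denominator n−1).
Block methods rescale the whole column-processed block to balance blocks of
very different size: `unit_frobenius` (1/‖X_k‖_F, default — every block
carries equal total variance), `inverse_sqrt_ncols` (1/√p_k),
`largest_singular_value` (1/σ_max), `none`. All statistics are fitted once
on training data and replayed verbatim on new samples; anything else would
make train and test embeddings incomparable.

## Sparse path

Sparse blocks are held as S − L Rᵀ: a sparse matrix plus a dense low-rank
correction. Column centering contributes one rank-1 term (1⃗ c⃗ᵀ) and each
deflation appends one more (either (X a⃗)a⃗ᵀ or u⃗(u⃗ᵀX)), so a run with R
factors carries at most R+1 terms per block. Every product costs
O(nnz + (n+p)R) and nothing n×n or p×p is ever formed. The dense and sparse
paths agree to 1e-10; the test suite asserts both the agreement and, via an
allocation trace, the memory contract.

## Diagnostics

* **Variance explained** — λ_j/Σλ (scree over computed orders, default) or
  λ_j divided by the total inertia Σₖ‖X_k‖_F² of the preprocessed data.
  Both are exposed because the former always sums to 1 while the latter
  says how much of the data the embedding captures.
* **Block contributions** — squared weights w_k². Since ‖w⃗‖₂ = 1 each
  column is a probability vector over blocks.
* **Top features** — entries of the global loading column ranked by
  magnitude; ties break by block order then feature order, so output is
  deterministic.

## Out-of-sample embedding

With block-loading deflation, loadings of different orders are orthonormal
within each block, hence X_k^(j) a⃗_k^(j) = X_k^(1) a⃗_k^(j): the training
scores satisfy F = X_pp A exactly, where A stacks w_k a⃗_k over blocks. New
samples of the same features are embedded by applying the stored
preprocessing and multiplying by A. Under global-score deflation the
projector acts on the training sample space and no such identity holds, so
prediction raises an error there instead of returning an approximation.

## Eigendecomposition oracle

At the optimum a⃗_k ∝ X_kᵀu⃗, so the objective equals u⃗ᵀX Xᵀu⃗ and each
order is the dominant eigenpair of the (deflated) global cross-product.
The reference solver computes it by dense symmetric eigendecomposition of
the n×n matrix and reuses the production deflation rules. It is test-scale
only (guard at n ≤ 2000) and deliberately exempt from the solver's memory
contract. Comparisons are made after sign alignment; orders whose
eigenvalues are numerically zero on both sides are counted as agreeing, and
equivalence tests avoid near-degenerate spectra (relative gap < 1e-3 in the
random-instance tests), where eigenvectors are not identifiable.

## Synthetic data

`generate` draws X_k = T P_kᵀ + σE_k with T (n×r) having centered, mutually
orthogonal columns of strictly decreasing norms d₁ > … > d_r, P_k random
orthonormal, E_k standard Gaussian. Orthogonal score columns make the
noiseless spectrum analytically known (λ_j = d_j² for one block), and the
strict decrease enforces the eigen-gap that keeps factor matching
well-posed. Options: hard-thresholding the smallest entries to a target
sparsity (stored CSR), and a Poisson count mode for single-cell-shaped
fixtures. The generator does not emulate library-size effects, dropout, or
batch structure; passing recovery tests certifies the algorithm on the
stated model, not robustness to those artifacts.

Default conditions are bulk-like (n = 21 samples, three blocks, rank 4,
noise sd 0.3). Problem sizes used by the test suite and acceptance script
were chosen once as representative: random equivalence instances use
n ∈ [8, 30], 2–4 blocks of 3–50 features with spectrum d = (6, 4, 2.5) and
σ = 0.05; recovery runs use n = 21, blocks (8, 10, 12), d = (8, 5.5, 4);
the large sparse instance uses n = 5000, m = 2000 at 2% density with score
norms scaled to the matrix size (d₁ = 5000) so the planted spectrum stays
separated after thresholding.

## Limitations

* Missing values are rejected, not imputed; ragged sample sets are not
  aligned automatically.
* No count normalization (CPM, log1p) or feature selection — these belong
  upstream.
* CPCA-mode out-of-sample prediction is intentionally unsupported (above).
* Near-degenerate eigenvalue pairs make individual factors (not their
  span) unstable in any solver of this objective; interpret per-factor
  output accordingly.
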