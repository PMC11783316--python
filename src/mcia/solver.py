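"""Extended-NIPALS solver for multiple co-inertia analysis and consensus PCA.

One order of the decomposition maximizes

    sum_k cov^2(X_k a_k, X a)      subject to ||a_k||_2 = 1, ||w||_2 = 1,

where the covariance is implemented as a plain inner product (any 1/(n-1)
factor only rescales eigenvalues uniformly and cancels in every reported
proportion). The fixed-point iteration is

    (i)   a_k <- X_k^T u / ||X_k^T u||        per block
    (ii)  f_k <- X_k a_k                      block scores
    (iii) w_k <- f_k^T u,  w <- w / ||w||     block weights
    (iv)  f <- sum_k w_k f_k,  u <- f / ||f||

iterated until the change in u drops below tolerance. Substituting (i) into
the update shows u_new is proportional to X X^T u, i.e. the iteration is a
power method on the global cross-product: the objective sequence is
non-decreasing and the order-1 solution is the dominant eigenvector of X X^T.

Higher orders repeat the iteration on deflated data. MCIA deflates each block
by its own loading, X_k <- X_k (I - a_k a_k^T), giving orthonormal block
loadings across orders; CPCA instead deflates by the global score,
X_k <- (I - u u^T) X_k, giving orthogonal global scores.

Cost per iteration is O(nm) dense, O(nnz + (n+p)R) sparse; no n x n or p x p
matrix is ever materialized.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np

from . import _linalg as la
from .blocks import MultiBlock
from .exceptions import NoVarianceError, ValidationError
from .preprocess import PreprocessModel, PreprocessSpec, apply_preprocessor, fit_preprocessor

__all__ = [
    "DEFLATION_MODES",
    "SolverSettings",
    "OrderResult",
    "DecompositionResult",
    "solve_order",
    "objective_value",
    "deflate",
    "decompose",
    "assemble_global_loadings",
]

DEFLATION_MODES = ("block_loadings", "global_scores")

# a block whose X_k^T u norm falls below this times its Frobenius norm is
# treated as orthogonal to u for the current order (fully deflated blocks)
_BLOCK_ZERO_RTOL = 1e-13


@dataclass(frozen=True)
class SolverSettings:
    """Number of orders, deflation variant, and iteration controls."""

    num_orders: int = 10
    deflation_mode: str = "block_loadings"
    tolerance: float = 1e-12
    max_iterations: int = 1000

    def __post_init__(self):
        if self.num_orders < 1:
            raise ValidationError("num_orders must be >= 1")
        if self.deflation_mode not in DEFLATION_MODES:
            raise ValidationError(f"unknown deflation_mode {self.deflation_mode!r}")
        if not self.tolerance > 0:
            raise ValidationError("tolerance must be > 0")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")


@dataclass
class OrderResult:
    """Solution of one order j."""

    order: int
    block_loadings: list          # a_k, unit norm (or zero for dead blocks)
    block_scores: list            # f_k = X_k^(j) a_k
    weights: np.ndarray           # w, unit norm
    global_score: np.ndarray      # f = sum_k w_k f_k (unnormalized)
    eigenvalue: float             # lambda_j = sum_k (f_k^T u)^2 at the optimum
    iterations_used: int
    converged: bool
    objective_trace: list = field(default_factory=list)

    @property
    def score_direction(self) -> np.ndarray:
        """Unit vector along the global score (u at the fixed point)."""
        nrm = np.linalg.norm(self.global_score)
        if nrm == 0.0:
            return self.global_score
        return self.global_score / nrm


@dataclass
class DecompositionResult:
    """Full R-order decomposition plus everything needed downstream."""

    orders: list                      # OrderResult per order
    global_loadings: np.ndarray       # A, p x R: column j stacks w_k a_k
    global_scores: np.ndarray         # F, n x R
    block_scores: dict                # name -> n x R
    block_loadings: dict              # name -> p_k x R
    eigenvalues: np.ndarray
    settings: SolverSettings
    preprocess_model: PreprocessModel | None
    block_names: list
    feature_ids: dict                 # name -> list of ids
    sample_ids: list
    total_inertia: float              # sum_k ||X_k,pp||_F^2
    warnings: list = field(default_factory=list)

    @property
    def n_orders(self) -> int:
        return len(self.orders)

    @property
    def weights(self) -> np.ndarray:
        """N x R matrix of block weight vectors."""
        return np.column_stack([o.weights for o in self.orders])


def _initial_direction(blocks: list) -> np.ndarray:
    """Column of the current global matrix with the largest norm, normalized."""
    best = (-1.0, 0, 0)  # (norm_sq, block index, column index)
    for k, M in enumerate(blocks):
        cn = la.colnorms_sq(M)
        j = int(np.argmax(cn))
        if cn[j] > best[0]:
            best = (float(cn[j]), k, j)
    norm_sq, k, j = best
    if norm_sq <= 0.0:
        raise NoVarianceError("no variance remaining")
    e = np.zeros(blocks[k].shape[1])
    e[j] = 1.0
    u = la.matvec(blocks[k], e)
    nrm = np.linalg.norm(u)
    if nrm == 0.0:
        raise NoVarianceError("no variance remaining")
    return u / nrm


def _orient(res: OrderResult) -> OrderResult:
    """Deterministic sign convention.

    Each a_k is flipped so its largest-magnitude entry is positive (flipping
    f_k and w_k with it leaves f unchanged); then, if the largest-magnitude
    entry of f is negative, w and f are flipped together (A and F stay
    consistent: F = X A).
    """
    w = res.weights.copy()
    for k, a in enumerate(res.block_loadings):
        if a.size and np.any(a != 0.0):
            i = int(np.argmax(np.abs(a)))
            if a[i] < 0:
                res.block_loadings[k] = -a
                res.block_scores[k] = -res.block_scores[k]
                w[k] = -w[k]
    f = np.zeros_like(res.global_score)
    for k in range(len(w)):
        f += w[k] * res.block_scores[k]
    if np.any(f != 0.0):
        i = int(np.argmax(np.abs(f)))
        if f[i] < 0:
            w = -w
            f = -f
    res.weights = w
    res.global_score = f
    return res


def solve_order(mb: MultiBlock, settings: SolverSettings) -> OrderResult:
    """Solve one order on the current (possibly deflated) blocks.

    Raises :class:`NoVarianceError` when every block is numerically zero.
    Non-convergence within ``max_iterations`` is reported via the
    ``converged`` flag, not an exception.
    """
    blocks = [b.values for b in mb.blocks]
    N = len(blocks)
    frob = np.sqrt([max(la.frob_sq(M), 0.0) for M in blocks])
    u = _initial_direction(blocks)

    a = [np.zeros(M.shape[1]) for M in blocks]
    f = [np.zeros(mb.n_samples) for _ in blocks]
    w_raw = np.zeros(N)
    trace = []
    converged = False
    iterations = 0
    for it in range(1, settings.max_iterations + 1):
        iterations = it
        obj = 0.0
        for k, M in enumerate(blocks):
            g = la.rmatvec(M, u)
            gn = np.linalg.norm(g)
            obj += gn * gn
            if gn <= _BLOCK_ZERO_RTOL * max(frob[k], 1e-300):
                a[k] = np.zeros(M.shape[1])
                f[k] = np.zeros(mb.n_samples)
                w_raw[k] = 0.0
            else:
                a[k] = g / gn
                f[k] = la.matvec(M, a[k])
                w_raw[k] = float(f[k] @ u)
        trace.append(obj)
        wn = np.linalg.norm(w_raw)
        if wn == 0.0:
            raise NoVarianceError("no variance remaining")
        fg = np.zeros(mb.n_samples)
        for k in range(N):
            fg += w_raw[k] * f[k]
        fn = np.linalg.norm(fg)
        if fn == 0.0:
            raise NoVarianceError("no variance remaining")
        u_new = fg / fn
        if u_new @ u < 0:  # sign alignment before the convergence test
            u_new = -u_new
        delta = np.linalg.norm(u_new - u)
        u = u_new
        if delta < settings.tolerance:
            converged = True
            break

    # final quantities at the (approximate) fixed point
    lam = 0.0
    for k, M in enumerate(blocks):
        if np.any(a[k] != 0.0):
            f[k] = la.matvec(M, a[k])
            w_raw[k] = float(f[k] @ u)
            lam += w_raw[k] ** 2
        else:
            w_raw[k] = 0.0
    wn = np.linalg.norm(w_raw)
    if wn == 0.0:
        raise NoVarianceError("no variance remaining")
    w = w_raw / wn
    fg = np.zeros(mb.n_samples)
    for k in range(N):
        fg += w[k] * f[k]
    trace.append(lam)
    res = OrderResult(
        order=mb.deflation_step,
        block_loadings=a,
        block_scores=f,
        weights=w,
        global_score=fg,
        eigenvalue=float(lam),
        iterations_used=iterations,
        converged=converged,
        objective_trace=trace,
    )
    return _orient(res)


def objective_value(mb: MultiBlock, block_loadings: list, u: np.ndarray) -> float:
    """sum_k (u^T X_k a_k)^2 for given unit loadings and unit score direction."""
    total = 0.0
    for b, a in zip(mb.blocks, block_loadings):
        a = np.asarray(a, dtype=float)
        if a.shape[0] != b.n_features:
            raise ValidationError("loading length does not match block")
        total += float(la.matvec(b.values, a) @ u) ** 2
    return total


def deflate(mb: MultiBlock, res: OrderResult, mode: str) -> MultiBlock:
    """Remove the order's component before solving the next order.

    ``block_loadings`` (MCIA): X_k <- X_k (I - a_k a_k^T);
    ``global_scores`` (CPCA):  X_k <- (I - u u^T) X_k with u = f/||f||.
    """
    if mode not in DEFLATION_MODES:
        raise ValidationError(f"unknown deflation mode {mode!r}")
    if mode == "block_loadings":
        new_values = []
        for b, a in zip(mb.blocks, res.block_loadings):
            if np.any(a != 0.0):
                new_values.append(la.deflate_block_loading(b.values, a))
            else:
                new_values.append(b.values)
    else:
        nrm = np.linalg.norm(res.global_score)
        if nrm == 0.0:
            raise NoVarianceError("zero global score; cannot deflate")
        u = res.global_score / nrm
        new_values = [la.deflate_global_score(b.values, u) for b in mb.blocks]
    return mb.replace_values(new_values, deflation_step=mb.deflation_step + 1)


def assemble_global_loadings(order_results: list) -> np.ndarray:
    """p x R matrix A whose column j stacks w_k^(j) a_k^(j) over blocks."""
    cols = []
    sizes = [a.shape[0] for a in order_results[0].block_loadings]
    for res in order_results:
        if [a.shape[0] for a in res.block_loadings] != sizes:
            raise ValidationError("inconsistent feature schema across orders")
        cols.append(
            np.concatenate([w * a for w, a in zip(res.weights, res.block_loadings)])
        )
    return np.column_stack(cols)


def _zero_order(mb: MultiBlock, j: int) -> OrderResult:
    return OrderResult(
        order=j,
        block_loadings=[np.zeros(b.n_features) for b in mb.blocks],
        block_scores=[np.zeros(mb.n_samples) for _ in mb.blocks],
        weights=np.zeros(mb.n_blocks),
        global_score=np.zeros(mb.n_samples),
        eigenvalue=0.0,
        iterations_used=0,
        converged=True,
        objective_trace=[0.0],
    )


def decompose(
    mb: MultiBlock,
    spec: PreprocessSpec | None = None,
    settings: SolverSettings | None = None,
) -> DecompositionResult:
    """Preprocess, then alternate solve_order / deflate for R orders.

    If the data's variance is exhausted before order R (rank deficiency), the
    remaining orders are recorded as zero orders and a warning is attached to
    the result.
    """
    spec = spec or PreprocessSpec()
    settings = settings or SolverSettings()
    R = settings.num_orders
    bound = min(mb.n_samples, mb.n_features_total)
    if R > bound:
        raise ValidationError(
            f"num_orders={R} exceeds min(n, p)={bound}"
        )
    model = fit_preprocessor(mb, spec)
    current = apply_preprocessor(model, mb)
    total_inertia = sum(la.frob_sq(b.values) for b in current.blocks)

    orders = []
    notes = []
    for j in range(1, R + 1):
        try:
            res = solve_order(current, settings)
        except NoVarianceError:
            notes.append(
                f"rank exhausted after order {j - 1}; orders {j}..{R} are zero"
            )
            _warnings.warn(notes[-1], RuntimeWarning, stacklevel=2)
            for jj in range(j, R + 1):
                orders.append(_zero_order(current, jj))
            break
        orders.append(res)
        if not res.converged:
            notes.append(
                f"order {j}: not converged after {res.iterations_used} iterations"
            )
        if j < R:
            current = deflate(current, res, settings.deflation_mode)

    A = assemble_global_loadings(orders)
    F = np.column_stack([o.global_score for o in orders])
    names = mb.block_names
    block_scores = {
        name: np.column_stack([o.block_scores[k] for o in orders])
        for k, name in enumerate(names)
    }
    block_loadings = {
        name: np.column_stack([o.block_loadings[k] for o in orders])
        for k, name in enumerate(names)
    }
    return DecompositionResult(
        orders=orders,
        global_loadings=A,
        global_scores=F,
        block_scores=block_scores,
        block_loadings=block_loadings,
        eigenvalues=np.array([o.eigenvalue for o in orders]),
        settings=settings,
        preprocess_model=model,
        block_names=names,
        feature_ids={b.name: list(b.feature_ids) for b in mb.blocks},
        sample_ids=list(mb.sample_ids),
        total_inertia=float(total_inertia),
        warnings=notes,
    )
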