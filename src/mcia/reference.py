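"""Direct-eigendecomposition solver of the same objective.

At the optimum of one order the block loadings satisfy a_k ~ X_k^T u, so the
objective collapses to u^T X X^T u: the order's score direction is the
dominant eigenvector of the global cross-product matrix. This module solves
each order that way — dense symmetric eigendecomposition of the n x n matrix
X X^T — and reuses the solver's deflation rules for higher orders.

It exists as an independent correctness oracle for the iterative solver and
is deliberately test-scale only (n x n is materialized; refuse n > 2000).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from ._linalg import to_dense
from .blocks import MultiBlock
from .exceptions import NoVarianceError, ValidationError
from .preprocess import PreprocessSpec, apply_preprocessor, fit_preprocessor
from .solver import (
    DecompositionResult,
    OrderResult,
    SolverSettings,
    _orient,
    _zero_order,
    assemble_global_loadings,
    deflate,
)

__all__ = [
    "EquivalenceReport",
    "reference_order",
    "reference_decompose",
    "compare_decompositions",
]

_MAX_ORACLE_N = 2000
_ZERO_RTOL = 1e-13


@dataclass
class EquivalenceReport:
    """Per-order agreement of two decompositions, up to sign and scale."""

    score_cosines: np.ndarray        # |cos| between global score columns
    eigenvalue_rel_diffs: np.ndarray
    max_loading_angle: float         # largest principal angle over blocks (rad)
    tol_cos: float
    tol_eig: float
    passed: bool

    def __str__(self):
        lines = ["order  |cos(score)|   eigenvalue rel. diff"]
        for j, (c, d) in enumerate(
            zip(self.score_cosines, self.eigenvalue_rel_diffs), start=1
        ):
            lines.append(f"{j:5d}  {c:.12f}  {d:.3e}")
        lines.append(f"max block-loading subspace angle: {self.max_loading_angle:.3e} rad")
        lines.append(f"passed: {self.passed} (tol_cos={self.tol_cos}, tol_eig={self.tol_eig})")
        return "\n".join(lines)


def reference_order(mb: MultiBlock):
    """Dominant eigenpair of X X^T plus the induced block loadings.

    Returns ``(u, eigenvalue, block_loadings)`` with unit ``u``.
    """
    n = mb.n_samples
    if n > _MAX_ORACLE_N:
        raise ValidationError(f"oracle is test-scale only (n={n} > {_MAX_ORACLE_N})")
    dense_blocks = [to_dense(b.values) for b in mb.blocks]
    X = np.hstack(dense_blocks)
    scale = np.linalg.norm(X)
    if scale == 0.0:
        raise NoVarianceError("no variance remaining")
    C = X @ X.T
    vals, vecs = scipy.linalg.eigh(C)
    lam = float(vals[-1])
    u = vecs[:, -1]
    loadings = []
    for Xk in dense_blocks:
        g = Xk.T @ u
        gn = np.linalg.norm(g)
        if gn <= _ZERO_RTOL * max(np.linalg.norm(Xk), 1e-300):
            loadings.append(np.zeros(Xk.shape[1]))
        else:
            loadings.append(g / gn)
    return u, lam, loadings


def _order_from_eigen(mb: MultiBlock) -> OrderResult:
    u, lam, loadings = reference_order(mb)
    scores = [to_dense(b.values) @ a for b, a in zip(mb.blocks, loadings)]
    w_raw = np.array([f @ u for f in scores])
    wn = np.linalg.norm(w_raw)
    if wn == 0.0:
        raise NoVarianceError("no variance remaining")
    w = w_raw / wn
    f = sum(wk * fk for wk, fk in zip(w, scores))
    res = OrderResult(
        order=mb.deflation_step,
        block_loadings=loadings,
        block_scores=scores,
        weights=w,
        global_score=np.asarray(f),
        eigenvalue=float(np.sum(w_raw**2)),
        iterations_used=0,
        converged=True,
        objective_trace=[float(np.sum(w_raw**2))],
    )
    return _orient(res)


def reference_decompose(
    mb: MultiBlock,
    settings: SolverSettings,
    spec: PreprocessSpec | None = None,
) -> DecompositionResult:
    """Eigendecomposition analog of :func:`mcia.solver.decompose`.

    ``spec=None`` skips preprocessing (identity transform is still fitted so
    the result schema matches).
    """
    spec = spec or PreprocessSpec("none", "none")
    R = settings.num_orders
    model = fit_preprocessor(mb, spec)
    current = apply_preprocessor(model, mb)
    from ._linalg import frob_sq

    total_inertia = sum(frob_sq(b.values) for b in current.blocks)
    orders, notes = [], []
    for j in range(1, R + 1):
        try:
            res = _order_from_eigen(current)
        except NoVarianceError:
            notes.append(f"rank exhausted after order {j - 1}")
            for jj in range(j, R + 1):
                orders.append(_zero_order(current, jj))
            break
        orders.append(res)
        if j < R:
            current = deflate(current, res, settings.deflation_mode)
    A = assemble_global_loadings(orders)
    F = np.column_stack([o.global_score for o in orders])
    names = mb.block_names
    return DecompositionResult(
        orders=orders,
        global_loadings=A,
        global_scores=F,
        block_scores={
            name: np.column_stack([o.block_scores[k] for o in orders])
            for k, name in enumerate(names)
        },
        block_loadings={
            name: np.column_stack([o.block_loadings[k] for o in orders])
            for k, name in enumerate(names)
        },
        eigenvalues=np.array([o.eigenvalue for o in orders]),
        settings=settings,
        preprocess_model=model,
        block_names=names,
        feature_ids={b.name: list(b.feature_ids) for b in mb.blocks},
        sample_ids=list(mb.sample_ids),
        total_inertia=float(total_inertia),
        warnings=notes,
    )


def compare_decompositions(
    d1: DecompositionResult,
    d2: DecompositionResult,
    tol_cos: float = 1e-8,
    tol_eig: float = 1e-6,
) -> EquivalenceReport:
    """Sign- and scale-insensitive agreement report between two results.

    Orders whose eigenvalue is numerically zero in both results are counted
    as agreeing (the score direction is not defined there).
    """
    if d1.global_scores.shape != d2.global_scores.shape:
        raise ValidationError("shape mismatch between decompositions")
    R = d1.n_orders
    lam_scale = max(float(np.max(d1.eigenvalues, initial=0.0)),
                    float(np.max(d2.eigenvalues, initial=0.0)), 1e-300)
    cosines = np.zeros(R)
    rel = np.zeros(R)
    for j in range(R):
        f1, f2 = d1.global_scores[:, j], d2.global_scores[:, j]
        n1, n2 = np.linalg.norm(f1), np.linalg.norm(f2)
        if n1 == 0.0 and n2 == 0.0:
            cosines[j] = 1.0
        elif n1 == 0.0 or n2 == 0.0:
            cosines[j] = 0.0
        else:
            cosines[j] = abs(float(f1 @ f2)) / (n1 * n2)
        l1, l2 = d1.eigenvalues[j], d2.eigenvalues[j]
        denom = max(abs(l1), abs(l2))
        if denom <= 1e-12 * lam_scale:
            rel[j] = 0.0
        else:
            rel[j] = abs(l1 - l2) / denom
    max_angle = 0.0
    for name in d1.block_names:
        A1, A2 = d1.block_loadings[name], d2.block_loadings[name]
        if np.linalg.matrix_rank(A1) == 0 or np.linalg.matrix_rank(A2) == 0:
            continue
        angles = scipy.linalg.subspace_angles(A1, A2)
        if angles.size:
            max_angle = max(max_angle, float(angles[0]))
    passed = bool(np.all(cosines >= 1.0 - tol_cos) and np.all(rel <= tol_eig))
    return EquivalenceReport(
        score_cosines=cosines,
        eigenvalue_rel_diffs=rel,
        max_loading_angle=max_angle,
        tol_cos=tol_cos,
        tol_eig=tol_eig,
        passed=passed,
    )
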