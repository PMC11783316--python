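"""Post-decomposition summaries: scree proportions, block contributions,
top features."""

from __future__ import annotations

import numpy as np

from .exceptions import ValidationError
from .solver import DecompositionResult

__all__ = ["variance_explained", "block_contributions", "top_features"]

VARIANCE_BASES = ("computed_orders", "total_data_variance")


def variance_explained(
    result: DecompositionResult, basis: str = "computed_orders"
) -> np.ndarray:
    """Proportion of variance explained by each order.

    ``computed_orders`` normalizes the eigenvalues over the R computed orders
    (the usual scree plot); ``total_data_variance`` divides each eigenvalue by
    the total inertia of the preprocessed data, sum_k ||X_k||_F^2, so the
    proportions need not sum to one.
    """
    if basis not in VARIANCE_BASES:
        raise ValidationError(f"unknown basis {basis!r}")
    lam = np.asarray(result.eigenvalues, dtype=float)
    if basis == "computed_orders":
        total = lam.sum()
        if total <= 0.0:
            raise ValidationError("all eigenvalues are zero")
        return lam / total
    if result.total_inertia <= 0.0:
        raise ValidationError("total inertia is zero")
    return lam / result.total_inertia


def block_contributions(result: DecompositionResult) -> np.ndarray:
    """N x R matrix of squared block weights; each nonzero column sums to 1."""
    return result.weights**2


def top_features(result: DecompositionResult, order: int, count: int) -> list:
    """The ``count`` features with largest |loading| on a given order.

    Returns ``(block name, feature id, loading value)`` tuples, descending by
    magnitude; ties break by block order then within-block feature order.
    """
    if not 1 <= order <= result.n_orders:
        raise ValidationError(f"order {order} out of range 1..{result.n_orders}")
    if count < 1:
        raise ValidationError("count must be >= 1")
    col = result.global_loadings[:, order - 1]
    labels = [
        (name, fid)
        for name in result.block_names
        for fid in result.feature_ids[name]
    ]
    idx = sorted(range(len(col)), key=lambda i: (-abs(col[i]), i))
    return [(labels[i][0], labels[i][1], float(col[i])) for i in idx[:count]]
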