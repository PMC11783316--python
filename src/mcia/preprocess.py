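"""Block preprocessing: within-block column transforms and whole-block weights.

Column options center or standardize each feature; block options rescale each
whole block to balance blocks of very different size or magnitude (the usual
concern when mixing, say, a 30-feature protein panel with a 20 000-gene
expression matrix). Fitted statistics are stored so the identical transform
can be replayed on held-out samples for out-of-sample embedding.

Sparse blocks are never densified: column scaling and block weighting act on
the stored sparse matrix, while centering is carried as an implicit rank-1
correction (see :mod:`mcia._linalg`). Results agree with the explicit dense
transform to 1e-10.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from ._linalg import SparseLowRank, sigma_max, to_dense
from .blocks import MultiBlock
from .exceptions import DegenerateBlockError, SchemaMismatchError, ValidationError

__all__ = [
    "COLUMN_METHODS",
    "BLOCK_METHODS",
    "PreprocessSpec",
    "BlockStats",
    "PreprocessModel",
    "fit_preprocessor",
    "apply_preprocessor",
]

COLUMN_METHODS = ("none", "center", "standardize")
BLOCK_METHODS = ("none", "unit_frobenius", "inverse_sqrt_ncols", "largest_singular_value")

# relative floor below which a column counts as constant (scale forced to 1)
_ZERO_VAR_RTOL = 1e-12


@dataclass(frozen=True)
class PreprocessSpec:
    """Choice of column method and whole-block weighting method."""

    column_method: str = "center"
    block_method: str = "unit_frobenius"

    def __post_init__(self):
        if self.column_method not in COLUMN_METHODS:
            raise ValidationError(f"unknown column_method {self.column_method!r}")
        if self.block_method not in BLOCK_METHODS:
            raise ValidationError(f"unknown block_method {self.block_method!r}")


@dataclass
class BlockStats:
    """Fitted per-block transform: x -> block_weight * (x - center) / scale."""

    name: str
    feature_ids: list
    column_centers: np.ndarray
    column_scales: np.ndarray
    block_weight: float


@dataclass
class PreprocessModel:
    spec: PreprocessSpec
    blocks: list = field(default_factory=list)  # BlockStats, in block order
    fitted_on: int = 0

    def stats_for(self, name: str) -> BlockStats:
        for s in self.blocks:
            if s.name == name:
                return s
        raise KeyError(name)


def _column_moments(values):
    """(mean, sample sd with ddof=1) per column, sparse-aware."""
    n = values.shape[0]
    if sp.issparse(values):
        mean = np.asarray(values.mean(axis=0)).ravel()
        sq = np.asarray(values.multiply(values).mean(axis=0)).ravel()
        var = np.maximum(sq - mean**2, 0.0) * (n / (n - 1))
    else:
        dense = np.asarray(values, dtype=float)
        mean = dense.mean(axis=0)
        var = dense.var(axis=0, ddof=1)
    return mean, np.sqrt(var)


def _processed_block_values(values, centers, scales, weight):
    """weight * (X - 1 c^T) / s, implicit for sparse inputs."""
    if sp.issparse(values):
        S = sp.csr_matrix(values.multiply(weight / scales))
        c = weight * centers / scales
        if np.any(c != 0.0):
            n = values.shape[0]
            return SparseLowRank(S, np.ones((n, 1)), c.reshape(-1, 1))
        return SparseLowRank(S)
    dense = np.asarray(values, dtype=float)
    return weight * (dense - centers) / scales


def fit_preprocessor(mb: MultiBlock, spec: PreprocessSpec) -> PreprocessModel:
    """Fit centers, scales, and block weights on (un-deflated) training data.

    Block weights are computed on the column-processed block:
    ``unit_frobenius`` -> 1/||X_k||_F, ``inverse_sqrt_ncols`` -> 1/sqrt(p_k),
    ``largest_singular_value`` -> 1/sigma_max(X_k), ``none`` -> 1.
    """
    model = PreprocessModel(spec=spec, fitted_on=mb.n_samples)
    for b in mb.blocks:
        p = b.n_features
        if spec.column_method == "none":
            centers = np.zeros(p)
            scales = np.ones(p)
        else:
            mean, sd = _column_moments(b.values)
            centers = mean
            if spec.column_method == "standardize":
                floor = _ZERO_VAR_RTOL * np.maximum(1.0, np.abs(mean))
                scales = np.where(sd > floor, sd, 1.0)
            else:
                scales = np.ones(p)

        processed = _processed_block_values(b.values, centers, scales, 1.0)
        if spec.block_method == "none":
            weight = 1.0
        elif spec.block_method == "inverse_sqrt_ncols":
            weight = 1.0 / np.sqrt(p)
        else:
            if spec.block_method == "unit_frobenius":
                from ._linalg import frob_sq

                norm = np.sqrt(frob_sq(processed))
            else:  # largest_singular_value
                norm = sigma_max(processed)
            if norm <= 0.0 or not np.isfinite(norm):
                raise DegenerateBlockError(
                    f"degenerate block {b.name!r}: no variance, block weight undefined"
                )
            weight = 1.0 / norm
        model.blocks.append(
            BlockStats(
                name=b.name,
                feature_ids=list(b.feature_ids),
                column_centers=np.asarray(centers, dtype=float),
                column_scales=np.asarray(scales, dtype=float),
                block_weight=float(weight),
            )
        )
    return model


def apply_preprocessor(model: PreprocessModel, mb: MultiBlock) -> MultiBlock:
    """Replay a fitted transform on ``mb`` (training data or new samples).

    The block schema (names, feature ids, order) must match the fit exactly;
    the sample count is free.
    """
    if [b.name for b in mb.blocks] != [s.name for s in model.blocks]:
        raise SchemaMismatchError("feature schema mismatch: block names/order differ")
    new_values = []
    for b, stats in zip(mb.blocks, model.blocks):
        if list(b.feature_ids) != stats.feature_ids:
            raise SchemaMismatchError(
                f"feature schema mismatch in block {b.name!r}"
            )
        new_values.append(
            _processed_block_values(
                b.values, stats.column_centers, stats.column_scales, stats.block_weight
            )
        )
    return mb.replace_values(new_values)


def dense_processed(model: PreprocessModel, mb: MultiBlock) -> list:
    """Explicit dense transform of every block (reference/test path)."""
    out = []
    for b, stats in zip(mb.blocks, model.blocks):
        dense = to_dense(b.values) if not sp.issparse(b.values) else b.values.toarray()
        out.append(
            stats.block_weight
            * (dense - stats.column_centers)
            / stats.column_scales
        )
    return out
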