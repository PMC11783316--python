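"""Multi-block data model.

A :class:`Block` is one omics view (samples x features); a :class:`MultiBlock`
is an ordered collection of blocks sharing the same ordered sample set. The
"global" matrix is the column-wise concatenation of the blocks. Feature
identity in the global matrix is the pair ``(block name, feature id)``, so
blocks may reuse feature names (e.g. shared gene symbols) without collision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from ._linalg import SparseLowRank, is_sparse_backend, to_dense
from .exceptions import ValidationError

__all__ = ["Block", "MultiBlock", "validate_multiblock", "concatenate", "split_global"]


def _check_finite(values) -> bool:
    if isinstance(values, SparseLowRank):
        return (
            bool(np.all(np.isfinite(values.S.data)))
            and bool(np.all(np.isfinite(values.L)))
            and bool(np.all(np.isfinite(values.R)))
        )
    if sp.issparse(values):
        return bool(np.all(np.isfinite(values.data)))
    return bool(np.all(np.isfinite(values)))


@dataclass
class Block:
    """One sample-by-feature data block.

    ``values`` may be a dense ndarray, a scipy sparse matrix, or a
    :class:`~mcia._linalg.SparseLowRank` (the solver's implicit sparse form).
    """

    name: str
    values: object
    sample_ids: Sequence[str]
    feature_ids: Sequence[str]

    def __post_init__(self):
        if not (sp.issparse(self.values) or isinstance(self.values, SparseLowRank)):
            self.values = np.asarray(self.values, dtype=float)
            if self.values.ndim != 2:
                raise ValidationError(f"block {self.name!r}: values must be 2-D")
        self.sample_ids = list(map(str, self.sample_ids))
        self.feature_ids = list(map(str, self.feature_ids))
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValidationError(f"block {self.name!r}: {len(self.sample_ids)} sample ids for {n} rows")
        if len(self.feature_ids) != p:
            raise ValidationError(f"block {self.name!r}: {len(self.feature_ids)} feature ids for {p} columns")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def is_sparse(self) -> bool:
        return sp.issparse(self.values) or is_sparse_backend(self.values)

    def dense_values(self) -> np.ndarray:
        if sp.issparse(self.values):
            return self.values.toarray()
        return to_dense(self.values)


@dataclass
class MultiBlock:
    """Ordered blocks over a shared sample set; ``deflation_step`` is 1 for
    original (un-deflated) data."""

    blocks: list = field(default_factory=list)
    deflation_step: int = 1

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def n_samples(self) -> int:
        return self.blocks[0].n_samples

    @property
    def sample_ids(self):
        return self.blocks[0].sample_ids

    @property
    def block_names(self):
        return [b.name for b in self.blocks]

    @property
    def n_features_total(self) -> int:
        return sum(b.n_features for b in self.blocks)

    @property
    def feature_counts(self):
        return [b.n_features for b in self.blocks]

    def __iter__(self):
        return iter(self.blocks)

    def __getitem__(self, key):
        if isinstance(key, str):
            for b in self.blocks:
                if b.name == key:
                    return b
            raise KeyError(key)
        return self.blocks[key]

    def replace_values(self, new_values: list, deflation_step: int | None = None) -> "MultiBlock":
        """Same schema, new matrices (used by preprocessing and deflation)."""
        blocks = [replace(b, values=v) for b, v in zip(self.blocks, new_values)]
        step = self.deflation_step if deflation_step is None else deflation_step
        return MultiBlock(blocks, deflation_step=step)


def validate_multiblock(blocks: Sequence[Block]) -> MultiBlock:
    """Validate blocks and assemble a :class:`MultiBlock` at deflation step 1.

    Raises
    ------
    ValidationError
        On an empty list, duplicate block names, samples unaligned across
        blocks, duplicate ids, non-finite values, or fewer than 2 samples.
    """
    blocks = list(blocks)
    if not blocks:
        raise ValidationError("no blocks given")
    names = [b.name for b in blocks]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate block names")
    ref = blocks[0].sample_ids
    if len(set(ref)) != len(ref):
        raise ValidationError("duplicate sample ids")
    if len(ref) < 2:
        raise ValidationError("at least 2 samples required")
    for b in blocks:
        if b.sample_ids != ref:
            raise ValidationError("samples unaligned across blocks")
        if b.n_features < 1:
            raise ValidationError(f"block {b.name!r}: at least one feature required")
        if len(set(b.feature_ids)) != len(b.feature_ids):
            raise ValidationError(f"block {b.name!r}: duplicate feature ids")
        if not _check_finite(b.values):
            raise ValidationError(f"block {b.name!r}: non-finite values")
    return MultiBlock(blocks, deflation_step=1)


def concatenate(mb: MultiBlock):
    """Column-wise concatenation ``X = [X_1 | ... | X_N]``.

    Dense blocks give a dense ndarray; if any block is sparse the result is
    sparse (CSR, or :class:`SparseLowRank` when implicit corrections are
    present), never implicitly densified.
    """
    vals = [b.values for b in mb.blocks]
    if len(vals) == 1:
        return vals[0]
    if any(isinstance(v, SparseLowRank) for v in vals):
        backs = [v if isinstance(v, SparseLowRank) else v for v in vals]
        S_parts, L_parts, R_rows = [], [], []
        k_total = sum(
            v.rank_correction if isinstance(v, SparseLowRank) else 0 for v in backs
        )
        p_off, k_off = 0, 0
        p_total = mb.n_features_total
        R = np.zeros((p_total, k_total))
        for v in backs:
            if isinstance(v, SparseLowRank):
                S_parts.append(v.S)
                k = v.rank_correction
                if k:
                    L_parts.append(v.L)
                    R[p_off : p_off + v.shape[1], k_off : k_off + k] = v.R
                    k_off += k
                p_off += v.shape[1]
            else:
                S_parts.append(sp.csr_matrix(v))
                p_off += v.shape[1]
        L = np.hstack(L_parts) if L_parts else None
        return SparseLowRank(sp.hstack(S_parts, format="csr"), L, R if k_total else None)
    if any(sp.issparse(v) for v in vals):
        return sp.hstack([sp.csr_matrix(v) if not sp.issparse(v) else v for v in vals], format="csr")
    return np.hstack(vals)


def split_global(X, mb: MultiBlock) -> list:
    """Split a global (n x p) dense matrix back at block boundaries."""
    X = np.asarray(X)
    out, off = [], 0
    for b in mb.blocks:
        out.append(X[:, off : off + b.n_features])
        off += b.n_features
    return out
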