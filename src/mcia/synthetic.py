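"""Synthetic multi-block data with known latent structure.

The generator draws a shared low-rank sample embedding and block-specific
orthonormal loadings:

    X_k = T P_k^T + sigma * E_k,

where T (n x r) has centered, mutually orthogonal columns with norms
d_1 > ... > d_r (a strictly decreasing spectrum keeps factor matching
well-posed), P_k (p_k x r) has orthonormal columns, and E_k is independent
standard Gaussian noise. Because the columns of T are orthogonal, a single
noiseless block has cross-product X X^T = T T^T with eigenvalues d_j^2 —
the generator's spectrum is analytically known, which is what makes
parameter-recovery tests sharp.

Defaults emulate a bulk multi-omics study: ~21 samples, three blocks with
feature counts spanning two orders of magnitude. A Poisson count mode is
available for single-cell-shaped fixtures. Real data is messier in ways the
generator does not imitate (library-size effects, dropout, batch structure);
tests passing here certify the algorithm, not robustness to those effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp

from .blocks import Block, validate_multiblock
from .exceptions import ValidationError

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate", "subspace_angle"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Shape, spectrum, and noise level of a synthetic multi-block dataset."""

    n_samples: int = 21
    feature_counts: tuple = (500, 120, 30)
    rank: int = 4
    score_scales: tuple = (10.0, 7.0, 5.0, 3.0)  # d_1 > ... > d_r
    noise_sd: float = 0.3
    sparsity: float = 0.0       # fraction of entries hard-thresholded to 0
    seed: int = 0
    count_noise: bool = False   # Poisson counts on exp-transformed signal

    def __post_init__(self):
        if self.n_samples < 2 or not self.feature_counts:
            raise ValidationError("need n >= 2 and at least one block")
        r = self.rank
        if r < 1 or r > min(self.n_samples, min(self.feature_counts)):
            raise ValidationError("rank must satisfy 1 <= r <= min(n, min p_k)")
        d = np.asarray(self.score_scales, dtype=float)
        if d.shape != (r,):
            raise ValidationError("score_scales must have length rank")
        if not (np.all(d > 0) and np.all(np.diff(d) < 0)):
            raise ValidationError("score_scales must be strictly decreasing and positive")
        if not 0.0 <= self.sparsity < 1.0:
            raise ValidationError("sparsity must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated dataset."""

    scores: np.ndarray            # T, n x r: centered orthogonal columns, norms d
    block_loadings: list = field(default_factory=list)  # P_k, orthonormal columns
    noise_sd: float = 0.0


def generate(spec: SyntheticSpec):
    """Draw one dataset; fully reproducible from ``spec.seed``.

    Returns ``(MultiBlock, SyntheticTruth)``. With ``sparsity > 0`` the
    smallest-magnitude entries of each block are zeroed and blocks are stored
    sparse (CSR).
    """
    rng = np.random.default_rng(spec.seed)
    n, r = spec.n_samples, spec.rank
    d = np.asarray(spec.score_scales, dtype=float)

    # centered orthogonal score columns with prescribed norms
    G = rng.standard_normal((n, r))
    G -= G.mean(axis=0)
    Q, _ = np.linalg.qr(G)
    T = Q[:, :r] * d

    blocks, loadings = [], []
    for k, p in enumerate(spec.feature_counts):
        Pk, _ = np.linalg.qr(rng.standard_normal((p, r)))
        Pk = Pk[:, :r]
        signal = T @ Pk.T
        if spec.count_noise:
            rate = np.exp(signal - signal.max())
            X = rng.poisson(rate * 10.0).astype(float)
        else:
            X = signal + spec.noise_sd * rng.standard_normal((n, p))
        if spec.sparsity > 0.0:
            cut = np.quantile(np.abs(X), spec.sparsity)
            X = np.where(np.abs(X) > cut, X, 0.0)
            X = sp.csr_matrix(X)
        blocks.append(
            Block(
                name=f"block{k + 1}",
                values=X,
                sample_ids=[f"s{i + 1}" for i in range(n)],
                feature_ids=[f"b{k + 1}_f{j + 1}" for j in range(p)],
            )
        )
        loadings.append(Pk)
    mb = validate_multiblock(blocks)
    return mb, SyntheticTruth(scores=T, block_loadings=loadings, noise_sd=spec.noise_sd)


def subspace_angle(U: np.ndarray, V: np.ndarray) -> float:
    """Largest principal angle (radians) between the column spans of U and V."""
    U = np.atleast_2d(np.asarray(U, dtype=float))
    V = np.atleast_2d(np.asarray(V, dtype=float))
    if np.linalg.matrix_rank(U) < U.shape[1] or np.linalg.matrix_rank(V) < V.shape[1]:
        raise ValidationError("rank-deficient input to subspace_angle")
    angles = scipy.linalg.subspace_angles(U, V)
    return float(angles[0]) if angles.size else 0.0
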