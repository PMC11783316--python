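"""Out-of-sample embedding of new samples into a fitted factor space.

With block-loading (MCIA) deflation the loadings of every order live in the
original feature space and are orthonormal within each block, so the global
scores of the training data satisfy F = X_pp A exactly. New samples of the
same features are therefore embedded by replaying the stored preprocessing
(training centers, scales, and block weights) and multiplying by A.

Global-score (CPCA) deflation projects in the training *sample* space, so
the same linear map is not exact there; prediction is refused rather than
approximated.
"""

from __future__ import annotations

import numpy as np

from . import _linalg as la
from .blocks import MultiBlock
from .exceptions import PredictionModeError
from .preprocess import apply_preprocessor
from .solver import DecompositionResult

__all__ = ["predict_global_scores"]


def predict_global_scores(
    result: DecompositionResult, new_mb: MultiBlock
) -> np.ndarray:
    """Project new samples onto the fitted global loadings.

    Parameters
    ----------
    result : DecompositionResult
        Must have been fitted with ``deflation_mode="block_loadings"``.
    new_mb : MultiBlock
        Same block names and feature ids as the training data, any number of
        samples.

    Returns
    -------
    ndarray, shape (n_new, R)
    """
    if result.settings.deflation_mode != "block_loadings":
        raise PredictionModeError(
            "prediction undefined for global-score deflation"
        )
    processed = apply_preprocessor(result.preprocess_model, new_mb)
    n_new = processed.n_samples
    R = result.global_loadings.shape[1]
    F = np.zeros((n_new, R))
    off = 0
    for b in processed.blocks:
        p_k = b.n_features
        A_k = result.global_loadings[off : off + p_k, :]
        F += np.column_stack(
            [la.matvec(b.values, A_k[:, j]) for j in range(R)]
        )
        off += p_k
    return F
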