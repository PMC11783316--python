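"""Model/Results front-end.

:class:`MCIA` is constructed from data plus options, like a statsmodels
model; :meth:`MCIA.fit` runs the NIPALS decomposition and returns an
:class:`MCIAResults` carrying scores, loadings, eigenvalues, diagnostics and
a text :meth:`~MCIAResults.summary`. Out-of-sample embedding hangs off the
results object.

Example
-------
>>> import numpy as np, pandas as pd
>>> from mcia import MCIA
>>> rng = np.random.default_rng(0)
>>> idx = [f"s{i}" for i in range(12)]
>>> rna = pd.DataFrame(rng.standard_normal((12, 30)), index=idx)
>>> prot = pd.DataFrame(rng.standard_normal((12, 8)), index=idx)
>>> res = MCIA({"rna": rna, "protein": prot}, n_factors=3).fit()
>>> res.global_scores.shape
(12, 3)
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .analysis import block_contributions, top_features, variance_explained
from .blocks import Block, MultiBlock, validate_multiblock
from .exceptions import ValidationError
from .io import write_result
from .predict import predict_global_scores
from .preprocess import PreprocessSpec
from .solver import DecompositionResult, SolverSettings, decompose

__all__ = ["MCIA", "MCIAResults"]


def _coerce_multiblock(blocks) -> MultiBlock:
    if isinstance(blocks, MultiBlock):
        return blocks
    if isinstance(blocks, dict):
        out = []
        index = None
        for name, data in blocks.items():
            if isinstance(data, pd.DataFrame):
                values = data.to_numpy(dtype=float)
                sample_ids = [str(s) for s in data.index]
                feature_ids = [str(c) for c in data.columns]
            elif sp.issparse(data) or isinstance(data, np.ndarray):
                values = data
                n, p = data.shape
                if index is None:
                    index = [f"sample_{i + 1}" for i in range(n)]
                sample_ids = index
                feature_ids = [f"{name}_{j + 1}" for j in range(p)]
            else:
                raise ValidationError(
                    f"block {name!r}: expected DataFrame, ndarray, or sparse matrix"
                )
            out.append(Block(name=str(name), values=values,
                             sample_ids=sample_ids, feature_ids=feature_ids))
        return validate_multiblock(out)
    raise ValidationError("blocks must be a MultiBlock or a dict of matrices")


class MCIA:
    """Multiple co-inertia analysis / consensus PCA of multi-block data.

    Parameters
    ----------
    blocks : dict or MultiBlock
        Mapping of block name to samples-by-features DataFrame / ndarray /
        sparse matrix; DataFrames must share an identically ordered index.
    n_factors : int
        Dimension R of the embedding (clamped to min(n, p)).
    deflation : {"block", "global"}
        ``"block"`` gives MCIA (orthonormal block loadings, supports
        out-of-sample prediction); ``"global"`` gives consensus PCA
        (orthogonal global scores).
    column_preprocess : {"none", "center", "standardize"}
    block_preprocess : {"none", "unit_frobenius", "inverse_sqrt_ncols",
        "largest_singular_value"}
        Whole-block weighting to balance blocks of different size/scale.
    tol, max_iter :
        Convergence tolerance on the score direction and the per-order
        iteration cap.
    """

    _DEFLATION = {"block": "block_loadings", "global": "global_scores",
                  "block_loadings": "block_loadings", "global_scores": "global_scores"}

    def __init__(self, blocks, n_factors: int = 10, deflation: str = "block",
                 column_preprocess: str = "center",
                 block_preprocess: str = "unit_frobenius",
                 tol: float = 1e-12, max_iter: int = 1000):
        self.data = _coerce_multiblock(blocks)
        if deflation not in self._DEFLATION:
            raise ValidationError(f"unknown deflation {deflation!r}")
        bound = min(self.data.n_samples, self.data.n_features_total)
        self.n_factors = min(int(n_factors), bound)
        if self.n_factors < 1:
            raise ValidationError("n_factors must be >= 1")
        self.preprocess_spec = PreprocessSpec(column_preprocess, block_preprocess)
        self.settings = SolverSettings(
            num_orders=self.n_factors,
            deflation_mode=self._DEFLATION[deflation],
            tolerance=tol,
            max_iterations=max_iter,
        )

    @classmethod
    def from_dataframes(cls, frames: dict, **kwargs) -> "MCIA":
        """Build from a dict of samples-by-features DataFrames."""
        return cls(frames, **kwargs)

    def fit(self) -> "MCIAResults":
        return MCIAResults(self, decompose(self.data, self.preprocess_spec, self.settings))


class MCIAResults:
    """Fitted decomposition with labeled accessors and diagnostics."""

    def __init__(self, model: MCIA, decomposition: DecompositionResult):
        self.model = model
        self.decomposition = decomposition

    # -- labeled views -----------------------------------------------------
    @property
    def _factors(self):
        return [f"factor_{j + 1}" for j in range(self.decomposition.n_orders)]

    @property
    def eigenvalues(self) -> pd.Series:
        return pd.Series(self.decomposition.eigenvalues, index=self._factors,
                         name="eigenvalue")

    @property
    def global_scores(self) -> pd.DataFrame:
        return pd.DataFrame(self.decomposition.global_scores,
                            index=self.decomposition.sample_ids,
                            columns=self._factors)

    @property
    def global_loadings(self) -> pd.DataFrame:
        d = self.decomposition
        index = pd.MultiIndex.from_tuples(
            [(name, fid) for name in d.block_names for fid in d.feature_ids[name]],
            names=["block", "feature"],
        )
        return pd.DataFrame(d.global_loadings, index=index, columns=self._factors)

    def block_scores(self, name: str) -> pd.DataFrame:
        d = self.decomposition
        return pd.DataFrame(d.block_scores[name], index=d.sample_ids,
                            columns=self._factors)

    def block_loadings(self, name: str) -> pd.DataFrame:
        d = self.decomposition
        return pd.DataFrame(d.block_loadings[name], index=d.feature_ids[name],
                            columns=self._factors)

    @property
    def weights(self) -> pd.DataFrame:
        return pd.DataFrame(self.decomposition.weights,
                            index=self.decomposition.block_names,
                            columns=self._factors)

    @property
    def converged(self) -> bool:
        return all(o.converged for o in self.decomposition.orders)

    @property
    def iterations(self) -> pd.Series:
        return pd.Series([o.iterations_used for o in self.decomposition.orders],
                         index=self._factors, name="iterations")

    # -- diagnostics -------------------------------------------------------
    def variance_explained(self, basis: str = "computed_orders") -> pd.Series:
        return pd.Series(variance_explained(self.decomposition, basis),
                         index=self._factors, name="proportion")

    def block_contributions(self) -> pd.DataFrame:
        return pd.DataFrame(block_contributions(self.decomposition),
                            index=self.decomposition.block_names,
                            columns=self._factors)

    def top_features(self, order: int = 1, count: int = 10) -> pd.DataFrame:
        rows = top_features(self.decomposition, order, count)
        return pd.DataFrame(rows, columns=["block", "feature", "loading"])

    # -- downstream --------------------------------------------------------
    def predict(self, new_blocks) -> pd.DataFrame:
        """Embed new samples of the same features (MCIA mode only)."""
        new_mb = _coerce_multiblock(new_blocks)
        F = predict_global_scores(self.decomposition, new_mb)
        return pd.DataFrame(F, index=new_mb.sample_ids, columns=self._factors)

    def save(self, directory) -> dict:
        """Write all result tables plus model.json; returns the manifest."""
        return write_result(self.decomposition, directory)

    def summary(self) -> str:
        d = self.decomposition
        mode = "MCIA (block-loading deflation)" \
            if d.settings.deflation_mode == "block_loadings" \
            else "CPCA (global-score deflation)"
        lines = [
            "Multi-block co-inertia decomposition",
            "=" * 60,
            f"method:            {mode}",
            f"samples:           {len(d.sample_ids)}",
            "blocks:            " + ", ".join(
                f"{name} ({len(d.feature_ids[name])} features)" for name in d.block_names
            ),
            f"factors:           {d.n_orders}",
            f"column preprocess: {d.preprocess_model.spec.column_method}",
            f"block preprocess:  {d.preprocess_model.spec.block_method}",
            f"converged:         {self.converged}",
            "",
            "factor   eigenvalue   prop.var   iterations",
        ]
        props = variance_explained(d, "computed_orders")
        for j, o in enumerate(d.orders):
            lines.append(
                f"{j + 1:6d}   {o.eigenvalue:10.6g}   {props[j]:8.4f}   {o.iterations_used:10d}"
            )
        lines.append("")
        lines.append("block contributions (squared weights):")
        lines.append(self.block_contributions().round(4).to_string())
        for note in d.warnings:
            lines.append(f"note: {note}")
        return "\n".join(lines)

    def __repr__(self):
        d = self.decomposition
        return (f"<MCIAResults: {len(d.sample_ids)} samples, "
                f"{len(d.block_names)} blocks, {d.n_orders} factors>")
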