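"""File I/O: block readers, result writers, and model serialization.

Blocks are read from delimited text (dense) or Matrix Market triplets with
sidecar feature/barcode files (sparse, 10x convention). Results are written
as delimited tables plus a JSON model file sufficient to re-run prediction;
no binary formats. All writers are deterministic: stable ordering and fixed
17-significant-digit float formatting.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .analysis import block_contributions, variance_explained
from .blocks import Block, MultiBlock, validate_multiblock
from .exceptions import ValidationError
from .preprocess import BlockStats, PreprocessModel, PreprocessSpec
from .solver import DecompositionResult, SolverSettings

__all__ = [
    "read_block_dense",
    "read_block_sparse",
    "write_block_dense",
    "write_result",
    "load_model",
]

_FLOAT_FMT = "%.17g"
ORIENTATIONS = ("samples_by_features", "features_by_samples")


def _delimiter_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_block_dense(path, name: str | None = None,
                     orientation: str = "samples_by_features") -> Block:
    """Read a dense block from CSV/TSV with a header row and row-name column.

    ``features_by_samples`` transposes on read (gene x sample convention).
    """
    if orientation not in ORIENTATIONS:
        raise ValidationError(f"unknown orientation {orientation!r}")
    path = Path(path)
    sep = _delimiter_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        raise ValidationError(f"{path}: duplicate ids")
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    if df.index.has_duplicates:
        raise ValidationError(f"{path}: duplicate ids")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: non-numeric cells") from exc
    if orientation == "features_by_samples":
        values = values.T
        sample_ids, feature_ids = list(df.columns), list(df.index)
    else:
        sample_ids, feature_ids = list(df.index), list(df.columns)
    return Block(
        name=name or path.stem,
        values=values,
        sample_ids=[str(s) for s in sample_ids],
        feature_ids=[str(f) for f in feature_ids],
    )


def read_block_sparse(matrix_path, features_path, barcodes_path,
                      name: str | None = None,
                      orientation: str = "features_by_samples") -> Block:
    """Read a sparse block from Matrix Market plus one-id-per-line files.

    Default orientation follows the 10x convention (features x barcodes).
    """
    if orientation not in ORIENTATIONS:
        raise ValidationError(f"unknown orientation {orientation!r}")
    M = sp.csr_matrix(scipy.io.mmread(matrix_path))
    features = [ln.strip() for ln in Path(features_path).read_text().splitlines() if ln.strip()]
    barcodes = [ln.strip() for ln in Path(barcodes_path).read_text().splitlines() if ln.strip()]
    if orientation == "features_by_samples":
        M = sp.csr_matrix(M.T)
        rows, cols = barcodes, features
        if M.shape != (len(barcodes), len(features)):
            raise ValidationError(
                f"{matrix_path}: matrix is {M.T.shape} but "
                f"{len(features)} features / {len(barcodes)} barcodes given"
            )
    else:
        rows, cols = barcodes, features
        if M.shape != (len(barcodes), len(features)):
            raise ValidationError(
                f"{matrix_path}: matrix is {M.shape} but "
                f"{len(barcodes)} barcodes / {len(features)} features given"
            )
    return Block(
        name=name or Path(matrix_path).stem,
        values=M,
        sample_ids=rows,
        feature_ids=cols,
    )


def write_block_dense(block: Block, path) -> None:
    """Write a block as samples-by-features delimited text."""
    path = Path(path)
    df = pd.DataFrame(
        block.dense_values(), index=block.sample_ids, columns=block.feature_ids
    )
    df.to_csv(path, sep=_delimiter_for(path), float_format=_FLOAT_FMT)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_result(result: DecompositionResult, directory) -> dict:
    """Write all result tables plus ``model.json``; returns the manifest.

    Files: global_scores.tsv, global_loadings.tsv (block/feature/factor
    long format), per-block block_scores_<name>.tsv and
    block_loadings_<name>.tsv, eigenvalues.tsv, block_contributions.tsv,
    variance_explained.tsv, model.json, manifest.json.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    R = result.n_orders
    factors = [f"factor_{j + 1}" for j in range(R)]
    written = []

    def _write_df(df: pd.DataFrame, fname: str, index_label=None):
        p = directory / fname
        df.to_csv(p, sep="\t", float_format=_FLOAT_FMT, index_label=index_label)
        written.append(p)

    _write_df(
        pd.DataFrame(result.global_scores, index=result.sample_ids, columns=factors),
        "global_scores.tsv", index_label="sample",
    )
    rows = []
    off = 0
    for name in result.block_names:
        for i, fid in enumerate(result.feature_ids[name]):
            rows.append([name, fid] + list(result.global_loadings[off + i]))
        off += len(result.feature_ids[name])
    _write_df(
        pd.DataFrame(rows, columns=["block", "feature"] + factors).set_index("block"),
        "global_loadings.tsv",
    )
    for name in result.block_names:
        _write_df(
            pd.DataFrame(result.block_scores[name], index=result.sample_ids, columns=factors),
            f"block_scores_{name}.tsv", index_label="sample",
        )
        _write_df(
            pd.DataFrame(result.block_loadings[name], index=result.feature_ids[name], columns=factors),
            f"block_loadings_{name}.tsv", index_label="feature",
        )
    _write_df(
        pd.DataFrame({"eigenvalue": result.eigenvalues},
                     index=pd.Index(range(1, R + 1), name="order")),
        "eigenvalues.tsv",
    )
    _write_df(
        pd.DataFrame(block_contributions(result), index=result.block_names, columns=factors),
        "block_contributions.tsv", index_label="block",
    )
    _write_df(
        pd.DataFrame(
            {"proportion": variance_explained(result, "computed_orders")},
            index=pd.Index(range(1, R + 1), name="order"),
        ),
        "variance_explained.tsv",
    )

    model = {
        "format_version": 1,
        "settings": {
            "num_orders": result.settings.num_orders,
            "deflation_mode": result.settings.deflation_mode,
            "tolerance": result.settings.tolerance,
            "max_iterations": result.settings.max_iterations,
        },
        "preprocess": {
            "column_method": result.preprocess_model.spec.column_method,
            "block_method": result.preprocess_model.spec.block_method,
            "fitted_on": result.preprocess_model.fitted_on,
            "blocks": [
                {
                    "name": s.name,
                    "feature_ids": s.feature_ids,
                    "column_centers": s.column_centers.tolist(),
                    "column_scales": s.column_scales.tolist(),
                    "block_weight": s.block_weight,
                }
                for s in result.preprocess_model.blocks
            ],
        },
        "eigenvalues": result.eigenvalues.tolist(),
        "total_inertia": result.total_inertia,
        "sample_ids": result.sample_ids,
        "warnings": result.warnings,
        "files": {"global_loadings": "global_loadings.tsv",
                  "global_scores": "global_scores.tsv"},
    }
    model_path = directory / "model.json"
    model_path.write_text(json.dumps(model, indent=2, sort_keys=True))
    written.append(model_path)

    manifest = {p.name: _sha256(p) for p in sorted(written)}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def load_model(model_path) -> DecompositionResult:
    """Reload a serialized decomposition (enough to run prediction)."""
    model_path = Path(model_path)
    meta = json.loads(model_path.read_text())
    directory = model_path.parent
    settings = SolverSettings(
        num_orders=meta["settings"]["num_orders"],
        deflation_mode=meta["settings"]["deflation_mode"],
        tolerance=meta["settings"]["tolerance"],
        max_iterations=meta["settings"]["max_iterations"],
    )
    pp = meta["preprocess"]
    model = PreprocessModel(
        spec=PreprocessSpec(pp["column_method"], pp["block_method"]),
        fitted_on=pp["fitted_on"],
    )
    for s in pp["blocks"]:
        model.blocks.append(
            BlockStats(
                name=s["name"],
                feature_ids=list(s["feature_ids"]),
                column_centers=np.asarray(s["column_centers"], dtype=float),
                column_scales=np.asarray(s["column_scales"], dtype=float),
                block_weight=float(s["block_weight"]),
            )
        )
    loadings_df = pd.read_csv(directory / meta["files"]["global_loadings"], sep="\t")
    factors = [c for c in loadings_df.columns if c.startswith("factor_")]
    A = loadings_df[factors].to_numpy(dtype=float)
    scores_df = pd.read_csv(directory / meta["files"]["global_scores"], sep="\t", index_col=0)
    F = scores_df[factors].to_numpy(dtype=float)
    names = [s.name for s in model.blocks]
    feature_ids = {s.name: s.feature_ids for s in model.blocks}
    block_loadings = {}
    off = 0
    for name in names:
        p_k = len(feature_ids[name])
        block_loadings[name] = A[off : off + p_k, :]
        off += p_k
    eig = np.asarray(meta["eigenvalues"], dtype=float)
    return DecompositionResult(
        orders=[],
        global_loadings=A,
        global_scores=F,
        block_scores={},
        block_loadings=block_loadings,
        eigenvalues=eig,
        settings=settings,
        preprocess_model=model,
        block_names=names,
        feature_ids=feature_ids,
        sample_ids=list(scores_df.index.astype(str)),
        total_inertia=float(meta["total_inertia"]),
        warnings=list(meta.get("warnings", [])),
    )


def read_multiblock_config(block_args: list, sparse_args: list) -> MultiBlock:
    """Assemble a MultiBlock from CLI-style NAME=PATH specifications."""
    blocks = []
    for spec in block_args:
        if "=" not in spec:
            raise ValidationError(f"expected NAME=PATH, got {spec!r}")
        name, path = spec.split("=", 1)
        blocks.append(read_block_dense(path, name=name))
    for spec in sparse_args:
        if "=" not in spec:
            raise ValidationError(f"expected NAME=MTX,FEATURES,BARCODES, got {spec!r}")
        name, paths = spec.split("=", 1)
        parts = paths.split(",")
        if len(parts) != 3:
            raise ValidationError(f"expected NAME=MTX,FEATURES,BARCODES, got {spec!r}")
        blocks.append(read_block_sparse(parts[0], parts[1], parts[2], name=name))
    return validate_multiblock(blocks)
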