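"""Expressed-gene filtering, log2 transformation, quantile normalization.

A gene counts as expressed when its FPKM reaches ``min_fpkm`` (default 1.0,
boundary inclusive) in at least one sample. Quantile normalization maps every
sample onto the cross-sample mean of order statistics; tied values within a
sample receive the mean of the reference entries spanned by their tied rank
range, so column sums (and the grand mean) are preserved.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    SCALE_FPKM,
    SCALE_LOG2,
    SCALE_LOG2_QNORM,
    ExpressionMatrix,
)
from .errors import DataError, ParameterError, StateError


def filter_expressed(
    matrix: ExpressionMatrix, min_fpkm: float = 1.0
) -> ExpressionMatrix:
    """Keep genes with max-over-samples FPKM >= ``min_fpkm`` (gene order
    preserved). A zero-gene matrix passes through unchanged."""
    matrix.require_scale(SCALE_FPKM)
    if matrix.n_genes == 0:
        return ExpressionMatrix(matrix.data.copy(), SCALE_FPKM)
    keep = matrix.data.max(axis=1) >= min_fpkm
    return ExpressionMatrix(matrix.data.loc[keep].copy(), SCALE_FPKM)


def log2_transform(
    matrix: ExpressionMatrix, offset: float = 1.0
) -> ExpressionMatrix:
    """Map FPKM v to log2(v + offset)."""
    matrix.require_scale(SCALE_FPKM)
    if offset < 0:
        raise ParameterError("offset must be >= 0")
    values = matrix.values()
    if offset == 0 and values.size and (values == 0).any():
        raise DataError("zero FPKM requires a positive log2 offset")
    out = np.log2(values + offset)
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns),
        SCALE_LOG2,
    )


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the mean order-statistic distribution.

    After normalization all per-sample sorted vectors coincide (up to tie
    averaging) and per-gene within-sample ranks are preserved.
    """
    matrix.require_scale(SCALE_LOG2)
    if matrix.n_genes < 1:
        raise StateError("quantile normalization needs at least one gene")
    if matrix.n_samples < 2:
        raise StateError("quantile normalization needs at least two samples")
    X = matrix.values()
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        mapped = np.empty_like(reference)
        mapped[order] = reference
        # ties: average the reference values over each tied rank range
        out[:, j] = (
            pd.Series(mapped).groupby(col, sort=False).transform("mean").to_numpy()
        )
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns),
        SCALE_LOG2_QNORM,
    )


def preprocess(
    matrix: ExpressionMatrix, min_fpkm: float = 1.0, offset: float = 1.0
) -> ExpressionMatrix:
    """filter -> log2 -> quantile normalize, the standard chain."""
    return quantile_normalize(log2_transform(filter_expressed(matrix, min_fpkm), offset))
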