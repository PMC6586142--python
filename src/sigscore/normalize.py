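"""Log transformation and quantile normalization of expression matrices.

Quantile normalization follows the classic reference-distribution recipe:
sort each column, average across columns at each rank to form the reference,
then map every value back to the reference value at its within-column rank.
Ties within a column receive the mean of the reference values over the tied
rank span, so tied inputs stay tied on output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, ValidationError

__all__ = ["log_transform", "quantile_normalize"]


def log_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Return ``log2(v + pseudocount)`` of a raw matrix.

    The default pseudocount of 1 maps zero counts to exactly 0 on the log
    scale, the dominant RNA-seq convention.
    """
    if m.is_log:
        raise ValidationError("matrix is already log-transformed")
    values = m.values
    if values.min() < 0:
        raise ValidationError("cannot log-transform negative values")
    if pseudocount <= 0 and values.min() <= 0:
        raise ValidationError("pseudocount must be positive for zero counts")
    out = pd.DataFrame(np.log2(values.astype(float) + pseudocount),
                       index=m.data.index, columns=m.data.columns)
    return ExpressionMatrix(out, is_log=True, is_quantile_normalized=False)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Map every column onto the per-rank mean reference distribution.

    For tie-free columns the output column equals the reference exactly (so
    all column multisets coincide and a second application is a no-op); a
    tied span is assigned the mean of the reference over that span.
    """
    if m.n_samples < 2:
        raise ValidationError("quantile normalization requires at least 2 samples")
    X = m.values.astype(float)
    n_genes, n_samples = X.shape

    order = np.argsort(X, axis=0, kind="stable")
    sorted_X = np.take_along_axis(X, order, axis=0)
    reference = sorted_X.mean(axis=1)

    out = np.empty_like(X)
    for j in range(n_samples):
        col_sorted = sorted_X[:, j]
        # tie groups = runs of equal values in the sorted column
        boundaries = np.flatnonzero(np.diff(col_sorted) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n_genes]))
        group_sums = np.add.reduceat(reference, starts)
        group_means = group_sums / (ends - starts)
        mapped_sorted = np.repeat(group_means, ends - starts)
        col_out = np.empty(n_genes)
        col_out[order[:, j]] = mapped_sorted
        out[:, j] = col_out

    frame = pd.DataFrame(out, index=m.data.index, columns=m.data.columns)
    return ExpressionMatrix(frame, is_log=m.is_log, is_quantile_normalized=True)
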