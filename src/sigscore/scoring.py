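"""Per-sample biomarker scores and per-cell signature positivity.

Two score forms are implemented, corresponding to the two signature shapes:

* **two-set t-score** (repression-type, e.g. a PAX7 target-gene signature):
  within one sample, the Welch t-statistic contrasting the expression of the
  signature's up-regulated genes against its down-regulated genes,

      t = (m_up - m_down) / sqrt(s2_up/n_up + s2_down/n_down)

  with unbiased (n-1) variances.  Repression of the up targets drives the
  score negative in affected samples.

* **mean-expression score** (activation-type, e.g. a DUX4 target-gene
  signature): the arithmetic mean of log expression over the signature's
  up-regulated genes.

`score_matrix` routes each signature to the right form and assembles the
per-sample biomarker table (one row per sample, one column per signature,
plus the group label) — the Results.csv contract.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .matrix import (
    ExpressionMatrix,
    GeneSignature,
    SampleLabels,
    SignatureError,
    SigscoreError,
)

logger = logging.getLogger("sigscore")

__all__ = [
    "tscore_biomarker",
    "mean_expression_biomarker",
    "score_matrix",
    "mean_of_biomarkers",
    "call_positivity",
    "write_results",
    "read_results",
]

GROUP_COLUMN = "group"


def _signature_values(column: pd.Series, genes: frozenset) -> np.ndarray:
    present = column.index.intersection(list(genes))
    return column.loc[present].to_numpy(dtype=float)


def _welch_t(up: np.ndarray, down: np.ndarray, name: str, *, pooled: bool = False) -> float:
    n_up, n_down = len(up), len(down)
    if n_up < 2 or n_down < 2:
        raise SignatureError(
            f"signature {name!r}: need >=2 genes in each set to form a t-score "
            f"(got {n_up} up, {n_down} down)"
        )
    m_up, m_down = up.mean(), down.mean()
    v_up, v_down = up.var(ddof=1), down.var(ddof=1)
    if pooled:
        sp2 = ((n_up - 1) * v_up + (n_down - 1) * v_down) / (n_up + n_down - 2)
        se = np.sqrt(sp2 * (1 / n_up + 1 / n_down))
    else:
        se = np.sqrt(v_up / n_up + v_down / n_down)
    diff = m_up - m_down
    if se == 0.0:
        if diff == 0.0:
            logger.warning("signature %r: both gene sets constant and equal; t-score 0", name)
            return 0.0
        raise SigscoreError(
            f"signature {name!r}: degenerate variance (zero spread, unequal means)"
        )
    return float(diff / se)


def tscore_biomarker(
    column: pd.Series,
    sig: GeneSignature,
    *,
    pooled: bool = False,
) -> float:
    """Two-set t-score of one sample's log expression for a two-sided signature.

    ``pooled=True`` switches from Welch to the pooled-variance t for
    sensitivity checks; the Welch form is the default.
    """
    if not sig.is_two_sided:
        raise SignatureError(
            f"signature {sig.name!r} has no down-regulated set; use the "
            "mean-expression score"
        )
    up = _signature_values(column, sig.up_genes)
    down = _signature_values(column, sig.down_genes)
    return _welch_t(up, down, sig.name, pooled=pooled)


def mean_expression_biomarker(column: pd.Series, sig: GeneSignature) -> float:
    """Mean log expression of a signature's up-regulated genes in one sample."""
    up = _signature_values(column, sig.up_genes)
    if len(up) == 0:
        raise SignatureError(
            f"signature {sig.name!r}: no up-regulated genes present in the sample"
        )
    return float(up.mean())


def _score_signature(m: ExpressionMatrix, sig: GeneSignature, *, pooled: bool) -> np.ndarray:
    """Vectorized per-sample scores for one signature over all columns."""
    present = sig.restrict(m.gene_ids)
    up = m.data.loc[sorted(present.up_genes)].to_numpy(dtype=float)
    if not present.is_two_sided:
        return up.mean(axis=0)
    down = m.data.loc[sorted(present.down_genes)].to_numpy(dtype=float)
    n_up, n_down = up.shape[0], down.shape[0]
    if n_up < 2 or n_down < 2:
        raise SignatureError(
            f"signature {sig.name!r}: need >=2 present genes in each set "
            f"(got {n_up} up, {n_down} down)"
        )
    m_up, m_down = up.mean(axis=0), down.mean(axis=0)
    v_up, v_down = up.var(axis=0, ddof=1), down.var(axis=0, ddof=1)
    if pooled:
        sp2 = ((n_up - 1) * v_up + (n_down - 1) * v_down) / (n_up + n_down - 2)
        se = np.sqrt(sp2 * (1 / n_up + 1 / n_down))
    else:
        se = np.sqrt(v_up / n_up + v_down / n_down)
    diff = m_up - m_down
    degenerate = se == 0.0
    if np.any(degenerate & (diff != 0.0)):
        bad = m.sample_ids[degenerate & (diff != 0.0)][0]
        raise SigscoreError(
            f"signature {sig.name!r}: degenerate variance in sample {bad!r}"
        )
    if np.any(degenerate):
        logger.warning(
            "signature %r: %d sample(s) with constant equal gene sets scored 0",
            sig.name, int(degenerate.sum()),
        )
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, 0.0, diff / np.where(degenerate, 1.0, se))
    return t


def score_matrix(
    m: ExpressionMatrix,
    sigs,
    labels: SampleLabels | None = None,
    *,
    pooled: bool = False,
) -> pd.DataFrame:
    """Biomarker table: one row per sample, one score column per signature.

    Signatures with a down set get the two-set t-score, up-only signatures
    the mean-expression score, in the input signature order.  When labels
    are given a ``group`` column ("case"/"control") is appended.
    """
    if not m.is_log:
        raise SigscoreError(
            "score_matrix expects log-scale expression; apply log_transform first"
        )
    sig_list = list(sigs.values()) if isinstance(sigs, dict) else list(sigs)
    table = pd.DataFrame(index=m.sample_ids.copy())
    table.index.name = "sample"
    for sig in sig_list:
        try:
            table[sig.name] = _score_signature(m, sig, pooled=pooled)
        except SigscoreError as exc:
            raise type(exc)(f"scoring signature {sig.name!r} failed: {exc}") from exc
    if labels is not None:
        if labels.n_samples != m.n_samples:
            raise SigscoreError(
                f"labels cover {labels.n_samples} samples but matrix has {m.n_samples}"
            )
        table[GROUP_COLUMN] = labels.group_names()
    return table


def mean_of_biomarkers(table: pd.DataFrame, columns) -> pd.Series:
    """Per-sample arithmetic mean of the named score columns.

    Used to pool several activation signatures into one composite score.
    """
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise SigscoreError("unknown biomarker columns: " + ", ".join(missing))
    return table[list(columns)].mean(axis=1)


def call_positivity(
    m: ExpressionMatrix,
    sig: GeneSignature,
    min_genes: int = 1,
    detection_threshold: float = 0.0,
) -> pd.DataFrame:
    """Per-sample signature positivity calls.

    A sample (or cell) is positive when at least ``min_genes`` of the
    signature's up-regulated genes exceed ``detection_threshold``.  The
    default threshold 0 reads "detected" as any nonzero expression, so calls
    should be made on values where zero means undetected (counts or
    log2(count+1)), not on a quantile-normalized matrix.
    """
    if min_genes < 1:
        raise SigscoreError("min_genes must be >= 1")
    if detection_threshold < 0:
        raise SigscoreError("detection_threshold must be >= 0")
    present = sig.restrict(m.gene_ids)
    n_present = len(present.up_genes)
    if min_genes > n_present:
        raise SigscoreError(
            f"min_genes={min_genes} exceeds the {n_present} signature genes "
            f"present in the matrix for {sig.name!r}"
        )
    values = m.data.loc[sorted(present.up_genes)].to_numpy(dtype=float)
    n_detected = (values > detection_threshold).sum(axis=0)
    calls = pd.DataFrame(
        {
            "n_detected": n_detected.astype(int),
            "is_positive": n_detected >= min_genes,
        },
        index=m.sample_ids.copy(),
    )
    calls.index.name = "sample"
    return calls


def write_results(table: pd.DataFrame, path) -> None:
    """Serialize a biomarker table as Results.csv (deterministic ordering)."""
    table.to_csv(path)


def read_results(path) -> pd.DataFrame:
    table = pd.read_csv(path, index_col=0)
    table.index.name = "sample"
    return table
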