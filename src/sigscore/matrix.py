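"""Core containers: expression matrices, case/control labels and gene signatures.

The canonical in-memory layout follows the field convention: a genes x samples
:class:`pandas.DataFrame` with Ensembl-style gene identifiers as the row index
and sample (or cell) identifiers as columns.  :class:`ExpressionMatrix` wraps
that frame with two bits of normalization state (``is_log``,
``is_quantile_normalized``) so downstream scoring can refuse raw counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("sigscore")

__all__ = [
    "SigscoreError",
    "ValidationError",
    "SignatureError",
    "ExpressionMatrix",
    "SampleLabels",
    "GeneSignature",
]


class SigscoreError(ValueError):
    """Base class for all validation and contract errors raised by sigscore."""


class ValidationError(SigscoreError):
    """An input file or matrix violates a structural invariant."""


class SignatureError(SigscoreError):
    """A gene signature is malformed or insufficiently covered by a matrix."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values plus normalization state.

    Parameters
    ----------
    data:
        DataFrame with unique gene IDs as index and unique sample IDs as
        columns.  Values must be finite; when ``is_log`` is False they are
        interpreted as raw (count-like) values and must be non-negative.
    is_log:
        True once values are on a log2 scale.
    is_quantile_normalized:
        True once every column has been mapped onto the common reference
        distribution (exact for tie-free columns; tied spans carry span means).
    """

    data: pd.DataFrame
    is_log: bool = False
    is_quantile_normalized: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise ValidationError("expression data must be a pandas DataFrame")
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValidationError("expression matrix has no data rows or columns")
        dup_genes = self.data.index[self.data.index.duplicated()].unique()
        if len(dup_genes):
            raise ValidationError(
                "duplicate gene IDs: " + ", ".join(map(str, dup_genes[:10]))
            )
        dup_samples = self.data.columns[self.data.columns.duplicated()].unique()
        if len(dup_samples):
            raise ValidationError(
                "duplicate sample IDs: " + ", ".join(map(str, dup_samples[:10]))
            )
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression matrix contains non-numeric values")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite value at gene {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )
        if not self.is_log and values.min() < 0:
            bad = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative raw value at gene {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )

    # -- convenience views -------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise ValidationError("unknown sample IDs: " + ", ".join(map(str, missing[:10])))
        return ExpressionMatrix(
            self.data.loc[:, list(sample_ids)],
            is_log=self.is_log,
            is_quantile_normalized=self.is_quantile_normalized,
        )


@dataclass(frozen=True)
class SampleLabels:
    """Case/control assignment by column position.

    ``case_indices`` holds 0-based column positions internally; the on-disk
    label-file format is 1-based column numbers (matching the original app
    input, where listed columns are cases and the remainder controls).
    """

    case_indices: frozenset
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValidationError("need at least one sample")
        for i in self.case_indices:
            if not (0 <= i < self.n_samples):
                raise ValidationError(
                    f"case column index {i + 1} out of range for {self.n_samples} samples"
                )

    @property
    def binary(self) -> np.ndarray:
        """Per-sample label vector: case=1, control=0."""
        y = np.zeros(self.n_samples, dtype=int)
        y[sorted(self.case_indices)] = 1
        return y

    @property
    def n_cases(self) -> int:
        return len(self.case_indices)

    @property
    def n_controls(self) -> int:
        return self.n_samples - len(self.case_indices)

    def require_both_groups(self) -> None:
        if self.n_cases == 0 or self.n_controls == 0:
            raise ValidationError(
                "group comparison requires at least one case and one control "
                f"(got {self.n_cases} cases, {self.n_controls} controls)"
            )

    def group_names(self, case: str = "case", control: str = "control") -> np.ndarray:
        return np.where(self.binary == 1, case, control)


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set, split into up-regulated and optional down-regulated members.

    Signatures with a non-empty down set are scored with the within-sample
    two-set t-score (repression-type); up-only signatures with the mean of
    the up genes' log expression (activation-type).
    """

    name: str
    up_genes: frozenset
    down_genes: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.up_genes:
            raise SignatureError(f"signature {self.name!r}: up-regulated set is empty")
        overlap = self.up_genes & self.down_genes
        if overlap:
            raise SignatureError(
                f"signature {self.name!r}: genes in both up and down sets: "
                + ", ".join(sorted(map(str, overlap))[:10])
            )

    @property
    def is_two_sided(self) -> bool:
        return len(self.down_genes) > 0

    def restrict(self, gene_ids: pd.Index) -> "GeneSignature":
        """Intersect with the genes present in a matrix.

        Genes absent from the matrix are dropped with a logged warning and
        the resulting coverage fraction; zero coverage of the up set is an
        error (nothing left to score).
        """
        present = set(gene_ids)
        up = frozenset(g for g in self.up_genes if g in present)
        down = frozenset(g for g in self.down_genes if g in present)
        if not up:
            raise SignatureError(
                f"signature {self.name!r}: none of the {len(self.up_genes)} "
                "up-regulated genes are present in the matrix"
            )
        cov_up = len(up) / len(self.up_genes)
        cov_down = len(down) / len(self.down_genes) if self.down_genes else 1.0
        if cov_up < 1.0 or cov_down < 1.0:
            logger.warning(
                "signature %r: coverage up=%d/%d (%.1f%%), down=%d/%d (%.1f%%)",
                self.name, len(up), len(self.up_genes), 100 * cov_up,
                len(down), len(self.down_genes), 100 * cov_down,
            )
        return GeneSignature(self.name, up, down)
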