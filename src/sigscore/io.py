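"""Readers and writers for the plain-text interchange formats.

Three file types are supported, matching the original app's contract:

* expression tables — delimited text, header row of sample IDs, first column
  gene IDs (Ensembl-style), remaining cells numeric;
* gene sets — GMT lines (``name<TAB>description<TAB>member...``) where a
  ``<name>__up`` / ``<name>__down`` pair of lines forms one two-sided
  signature and a bare (or ``__up``-only) line an up-only signature;
* sample labels — a single column of 1-based column numbers naming the case
  samples, the remainder being controls.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import (
    ExpressionMatrix,
    GeneSignature,
    SampleLabels,
    SignatureError,
    ValidationError,
)

__all__ = [
    "read_expression_table",
    "write_expression_table",
    "read_gene_signatures",
    "write_gene_signatures",
    "read_sample_labels",
    "write_sample_labels",
]

_UP_SUFFIX = "__up"
_DOWN_SUFFIX = "__down"


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_table(
    path,
    delimiter: str | None = None,
    *,
    is_log: bool = False,
    is_quantile_normalized: bool = False,
) -> ExpressionMatrix:
    """Read a genes x samples expression table.

    The normalization flags are caller-declared: set ``is_log=True`` when the
    file already holds log-scale values (e.g. a pre-normalized public matrix).
    Errors name the offending gene/sample for duplicate IDs, non-numeric
    cells and ragged rows.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    sep = _infer_delimiter(path, delimiter)

    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=sep))
    rows = [r for r in rows if r and not all(c.strip() == "" for c in r)]
    if len(rows) < 2:
        raise ValidationError(f"{path}: no data rows")
    header = rows[0]
    sample_ids = [c.strip() for c in header[1:]]
    if not sample_ids:
        raise ValidationError(f"{path}: header has no sample columns")
    n_cols = len(sample_ids)

    gene_ids: list[str] = []
    values = np.empty((len(rows) - 1, n_cols), dtype=float)
    for i, row in enumerate(rows[1:], start=2):
        if len(row) - 1 != n_cols:
            raise ValidationError(
                f"{path}: ragged row {i}: expected {n_cols} values, got {len(row) - 1}"
            )
        gene_ids.append(row[0].strip())
        for j, cell in enumerate(row[1:]):
            try:
                values[i - 2, j] = float(cell)
            except ValueError:
                raise ValidationError(
                    f"{path}: non-numeric value {cell!r} at row {i} "
                    f"(gene {row[0].strip()!r}), column {sample_ids[j]!r}"
                ) from None

    frame = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                         columns=sample_ids)
    return ExpressionMatrix(frame, is_log=is_log,
                            is_quantile_normalized=is_quantile_normalized)


def write_expression_table(m: ExpressionMatrix, path, delimiter: str | None = None) -> None:
    """Write a matrix in the same layout ``read_expression_table`` accepts.

    Values are written with ``repr`` round-trip precision so a write/read
    cycle reproduces them exactly.
    """
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    frame = m.data.copy()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep=sep, float_format=None)


def read_gene_signatures(path) -> dict[str, GeneSignature]:
    """Parse a GMT file into named signatures (insertion-ordered).

    ``S__up``/``S__down`` line pairs are merged into one two-sided signature
    named ``S``; any other line becomes an up-only signature.  An empty up
    set or up/down overlap raises :class:`SignatureError`.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    up_sets: dict[str, frozenset] = {}
    down_sets: dict[str, frozenset] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 member"
                )
            raw_name, _desc, *members = fields
            members = frozenset(g.strip() for g in members if g.strip())
            if raw_name.endswith(_DOWN_SUFFIX):
                name = raw_name[: -len(_DOWN_SUFFIX)]
                if name in down_sets:
                    raise ValidationError(f"{path}:{lineno}: duplicate down set for {name!r}")
                down_sets[name] = members
            else:
                name = raw_name[: -len(_UP_SUFFIX)] if raw_name.endswith(_UP_SUFFIX) else raw_name
                if name in up_sets:
                    raise ValidationError(f"{path}:{lineno}: duplicate up set for {name!r}")
                up_sets[name] = members
            if name not in order:
                order.append(name)

    signatures: dict[str, GeneSignature] = {}
    for name in order:
        up = up_sets.get(name, frozenset())
        down = down_sets.get(name, frozenset())
        if not up:
            raise SignatureError(f"signature {name!r}: up-regulated set is empty")
        signatures[name] = GeneSignature(name, up, down)
    return signatures


def write_gene_signatures(signatures, path) -> None:
    """Write signatures as GMT using the ``__up``/``__down`` convention."""
    sigs = signatures.values() if isinstance(signatures, dict) else signatures
    with open(path, "w") as fh:
        for sig in sigs:
            fh.write("\t".join([f"{sig.name}__up", "up-regulated members",
                                *sorted(sig.up_genes)]) + "\n")
            if sig.down_genes:
                fh.write("\t".join([f"{sig.name}__down", "down-regulated members",
                                    *sorted(sig.down_genes)]) + "\n")


def read_sample_labels(path, n_samples: int) -> SampleLabels:
    """Read 1-based case column numbers (one per line) into labels."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    indices = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip()
            if not token:
                continue
            try:
                col = int(token)
            except ValueError:
                raise ValidationError(
                    f"{path}:{lineno}: expected a column number, got {token!r}"
                ) from None
            if not (1 <= col <= n_samples):
                raise ValidationError(
                    f"{path}:{lineno}: column number {col} out of range 1..{n_samples}"
                )
            indices.add(col - 1)
    if not indices:
        raise ValidationError(f"{path}: no case column numbers found")
    return SampleLabels(frozenset(indices), n_samples)


def write_sample_labels(labels: SampleLabels, path) -> None:
    with open(path, "w") as fh:
        for i in sorted(labels.case_indices):
            fh.write(f"{i + 1}\n")
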