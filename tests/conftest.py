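import numpy as np
import pandas as pd
import pytest

from sigscore import ExpressionMatrix, GeneSignature, SampleLabels


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def small_log_matrix(rng):
    """20 genes x 8 samples, log scale, deterministic."""
    genes = [f"ENSG{i:011d}" for i in range(1, 21)]
    samples = [f"s{i}" for i in range(1, 9)]
    values = rng.normal(6.0, 1.0, (20, 8))
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples),
                            is_log=True)


@pytest.fixture
def two_sided_sig():
    genes = [f"ENSG{i:011d}" for i in range(1, 21)]
    return GeneSignature("REP", frozenset(genes[:6]), frozenset(genes[6:12]))


@pytest.fixture
def up_only_sig():
    genes = [f"ENSG{i:011d}" for i in range(1, 21)]
    return GeneSignature("ACT", frozenset(genes[12:18]))


@pytest.fixture
def labels8():
    return SampleLabels(frozenset(range(4)), 8)


def write_expression_file(path, n_genes=3, n_samples=2, delimiter="\t", values=None):
    genes = [f"ENSG{i:011d}" for i in range(1, n_genes + 1)]
    samples = [f"s{i}" for i in range(1, n_samples + 1)]
    if values is None:
        values = np.arange(n_genes * n_samples, dtype=float).reshape(n_genes, n_samples)
    lines = [delimiter.join(["gene_id", *samples])]
    for g, row in zip(genes, values):
        lines.append(delimiter.join([g, *map(str, row)]))
    path.write_text("\n".join(lines) + "\n")
    return genes, samples, np.asarray(values, dtype=float)
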