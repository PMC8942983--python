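import numpy as np
import pandas as pd
import pytest

from cernanet.types import ExpressionMatrix


def make_matrix(counts, gene_classes, groups, genes=None, samples=None):
    """Build a small ExpressionMatrix from plain lists."""
    counts = np.asarray(counts, dtype=float)
    n_genes, n_samples = counts.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    samples = samples or [f"s{j}" for j in range(n_samples)]
    return ExpressionMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        rna_class=pd.Series(gene_classes, index=genes),
        group=pd.Series(groups, index=samples),
    )


@pytest.fixture
def tiny_matrix():
    """3 genes (one per class) x 4 samples (2 case, 2 control)."""
    return make_matrix(
        [[10, 12, 5, 6], [3, 4, 9, 8], [20, 22, 21, 19]],
        ["lncRNA", "miRNA", "mRNA"],
        ["case", "case", "control", "control"],
    )


def de_row(gene, rna_class, log2fc, adj_pvalue=0.01, pvalue=None):
    return {
        "gene": gene, "rna_class": rna_class, "log2fc": log2fc,
        "pvalue": adj_pvalue if pvalue is None else pvalue,
        "adj_pvalue": adj_pvalue,
        "direction": "up" if log2fc > 0 else "down",
    }


def de_table(rows):
    return pd.DataFrame(rows)


@pytest.fixture
def ranking_network():
    """Network realising the built-in top-lncRNA degree profile."""
    from cernanet.datasets import profile_network

    return profile_network()
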