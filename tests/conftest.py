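import numpy as np
import pandas as pd
import pytest

from coexdup.network import CoexpressionNetwork


def network_from_edges(edges, genes=None, cutoff=2.5):
    """Build a CoexpressionNetwork directly from an (g1, g2) edge list."""
    edges = list(edges)
    if genes is None:
        genes = sorted({g for e in edges for g in e})
    df = pd.DataFrame(
        {
            "gene1": [e[0] for e in edges],
            "gene2": [e[1] for e in edges],
            "z": [e[2] if len(e) > 2 else 3.0 for e in edges],
        }
    )
    return CoexpressionNetwork(
        gene_ids=list(genes),
        cutoff=cutoff,
        edges=df,
        fisher_mean=0.0,
        fisher_sd=1.0,
        n_scored_pairs=len(df),
    )


@pytest.fixture
def toy_network():
    # two triangles bridged by one edge, plus an isolated gene
    edges = [
        ("a", "b"), ("b", "c"), ("a", "c"),
        ("d", "e"), ("e", "f"), ("d", "f"),
        ("c", "d"),
    ]
    return network_from_edges(edges, genes=list("abcdefg"))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
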