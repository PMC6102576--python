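import numpy as np
import pytest

from rmvspc import ExpressionView, Network


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_views(rng):
    """Two tiny views over 8 genes with two clearly separated gene blocks.

    Genes 0-3 follow one latent sample profile, genes 4-7 another, in both
    views, so any reasonable module method splits them 4 + 4.
    """
    views = []
    for stage in (1, 2):
        base1 = rng.normal(size=12)
        base2 = rng.normal(size=12)
        cols = [base1 * rng.uniform(0.5, 2) for _ in range(4)]
        cols += [base2 * rng.uniform(0.5, 2) for _ in range(4)]
        values = np.column_stack(cols) + 0.01 * rng.normal(size=(12, 8))
        views.append(
            ExpressionView(
                stage_id=stage,
                values=values,
                gene_ids=[f"g{i}" for i in range(8)],
                sample_ids=[f"s{stage}_{j}" for j in range(12)],
            )
        )
    return views


@pytest.fixture
def toy_network():
    """Two 4-cliques over the 8 toy genes, no edges between the blocks."""
    A = np.zeros((8, 8))
    for block in (range(4), range(4, 8)):
        for i in block:
            for j in block:
                if i != j:
                    A[i, j] = 1.0
    return Network(adjacency=A, gene_ids=[f"g{i}" for i in range(8)])
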