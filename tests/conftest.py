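import numpy as np
import pytest

from gravgrn import DirectedGRN, make_fixture


@pytest.fixture
def worked_example_grn():
    """The 4-gene, 8-edge network whose transition matrix is known in closed form.

    Edges (order A,B,C,D = 0,1,2,3): A->B, A->C, B->A, B->D, C->A, C->D,
    D->A, D->B. Every gene has out-degree 2.
    """
    edges = {(0, 1), (0, 2), (1, 0), (1, 3), (2, 0), (2, 3), (3, 0), (3, 1)}
    return DirectedGRN(edges=frozenset(edges), n_genes=4)


@pytest.fixture(scope="session")
def tiny_dataset():
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def standard_dataset():
    return make_fixture("standard")


def random_digraph(n: int, p_edge: float, rng: np.random.Generator) -> DirectedGRN:
    """Erdos-Renyi style directed graph without self-loops."""
    mask = rng.random((n, n)) < p_edge
    np.fill_diagonal(mask, False)
    edges = frozenset((int(i), int(j)) for i, j in zip(*np.nonzero(mask)))
    return DirectedGRN(edges=edges, n_genes=n)
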