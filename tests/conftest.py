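import numpy as np
import pandas as pd
import pytest

from subpert import ExpressionMatrix, Pathway, PhenotypeLabels


@pytest.fixture
def triangle():
    return Pathway.from_edges("triangle", [("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def two_disjoint_edges():
    """High-z edge {A,B} plus weak edge {C,D}: the classic witness that the
    full edge set need not maximise the perturbation score."""
    pathway = Pathway.from_edges("pair", [("A", "B"), ("C", "D")])
    z = {"A": 3.0, "B": 3.0, "C": 0.1, "D": 0.1}
    return pathway, z


@pytest.fixture
def small_expression():
    """3 genes x 6 samples with one clearly shifted gene."""
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        rng.normal(size=(3, 6)),
        index=["g1", "g2", "g3"],
        columns=[f"s{i}" for i in range(6)],
    )
    data.loc["g1", ["s0", "s1", "s2"]] += 5.0
    expr = ExpressionMatrix(data)
    labels = PhenotypeLabels(
        assignments={f"s{i}": ("tumor" if i < 3 else "normal") for i in range(6)}
    )
    return expr, labels


def random_instance(rng, max_edges=12, name="inst"):
    """Small random pathway with iid standard-normal gene z-scores."""
    import networkx as nx

    n = int(rng.integers(5, 9))
    m = min(int(rng.integers(4, max_edges + 1)), n * (n - 1) // 2)
    g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
    pathway = Pathway.from_edges(name, [(f"g{u}", f"g{v}") for u, v in g.edges])
    z = {
        gene: float(v)
        for gene, v in zip(sorted(pathway.genes), rng.normal(size=pathway.n_genes))
    }
    return pathway, z
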