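import random

import numpy as np
import pandas as pd
import pytest

from lrinet import CoexpressionNetwork, MicroarrayExperimentSituation

WORKED_NODES = ("1", "2", "3", "4")
WORKED_EDGES = (("1", "2"), ("1", "3"), ("1", "4"), ("2", "3"))


@pytest.fixture
def worked_example() -> CoexpressionNetwork:
    """The 4-gene reference network g^E = {12, 13, 14, 23}."""
    return CoexpressionNetwork(WORKED_NODES, WORKED_EDGES)


def random_connected_network(
    rng: random.Random, max_genes: int = 8, max_links: int = 10
) -> CoexpressionNetwork:
    """Random connected simple graph with ≤ max_genes nodes and ≤ max_links
    edges (string node labels)."""
    import networkx as nx

    while True:
        n = rng.randint(2, max_genes)
        m = rng.randint(n - 1, min(max_links, n * (n - 1) // 2))
        g = nx.gnm_random_graph(n, m, seed=rng.randrange(2**31))
        if nx.is_connected(g):
            break
    nodes = [f"g{k}" for k in range(n)]
    return CoexpressionNetwork(nodes, [(f"g{a}", f"g{b}") for a, b in g.edges])


# case matrix whose pairwise |pearson r| exceeds 0.9 exactly for the pairs
# {12,13,14,23}: correlation network == the worked-example topology
FIXTURE_CASE_MATRIX = np.array(
    [
        [8.5000, 8.5000, 8.0000, 7.5000, 7.5000, 8.0000],
        [7.4813, 7.2795, 7.1009, 6.5187, 6.7205, 6.8991],
        [9.7398, 9.3728, 9.1835, 8.2602, 8.6272, 8.8165],
        [6.2796, 6.5549, 5.8624, 5.7204, 5.4451, 6.1376],
    ]
)


@pytest.fixture
def worked_example_mes() -> MicroarrayExperimentSituation:
    """Expression data whose case-correlation network at τ=0.9 is the
    worked-example topology."""
    genes = list(WORKED_NODES)
    rng = np.random.default_rng(7)
    case = pd.DataFrame(
        FIXTURE_CASE_MATRIX, index=genes, columns=[f"C{k}" for k in range(6)]
    )
    ctrl = pd.DataFrame(
        rng.normal(8.0, 0.5, (4, 6)), index=genes, columns=[f"N{k}" for k in range(6)]
    )
    return MicroarrayExperimentSituation(case, ctrl)
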