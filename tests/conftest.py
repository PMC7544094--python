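import numpy as np
import pytest

from telburden.tables_io import LDMatrix


@pytest.fixture
def chain_matrix():
    """Transitivity-ambiguous chain: A~B and B~C above cutoff, A!~C below."""
    r2 = np.array(
        [
            [1.0, 0.6, 0.1],
            [0.6, 1.0, 0.55],
            [0.1, 0.55, 1.0],
        ]
    )
    return LDMatrix(chromosome="chain", rsids=["rsA", "rsB", "rsC"], r2=r2)


def random_symmetric_r2(rng, n):
    """Random valid R^2 matrix with unit diagonal."""
    m = rng.uniform(0, 1, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    return m


class UnionFind:
    """Brute-force union-find oracle, independent of the graph implementation."""

    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def n_components(self):
        return len({self.find(x) for x in self.parent})


def union_find_cluster_count(matrix: LDMatrix, cutoff: float) -> int:
    """Double-loop threshold clustering via union-find (the oracle)."""
    uf = UnionFind(matrix.rsids)
    n = matrix.n
    for i in range(n):
        for j in range(n):
            if i != j and not np.isnan(matrix.r2[i, j]) and matrix.r2[i, j] >= cutoff:
                uf.union(matrix.rsids[i], matrix.rsids[j])
    return uf.n_components()
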