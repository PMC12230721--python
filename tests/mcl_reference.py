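"""Independent dense reference implementation of Markov clustering.

Written directly from the published description of the algorithm (alternate
matrix squaring and entrywise inflation of a column-stochastic matrix until
idempotence; clusters are the connected components of the limit matrix's
support).  Deliberately structured differently from the package
implementation — dense numpy arrays, idempotence-based stopping, and
component-based cluster extraction — so the two can serve as mutual checks.
"""

from __future__ import annotations

import numpy as np


def reference_mcl(
    adjacency: np.ndarray,
    inflation: float = 1.5,
    prune: float = 1e-5,
    max_iters: int = 200,
    self_loop: float = 1.0,
) -> list[set[int]]:
    """Cluster a dense symmetric adjacency matrix; returns index sets."""
    n = adjacency.shape[0]
    m = adjacency.astype(float).copy()
    np.fill_diagonal(m, self_loop)
    m /= m.sum(axis=0, keepdims=True)
    for _ in range(max_iters):
        expanded = m @ m
        inflated = expanded**inflation
        inflated[inflated < prune] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        inflated /= colsum
        if np.allclose(inflated, m, atol=1e-10):
            m = inflated
            break
        m = inflated

    # clusters: connected components of the limit support, attractor rows only
    support = m > 1e-6
    attractors = np.where(np.diag(m) > 1e-6)[0]
    # union-find over nodes sharing an attractor row
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    claimed = set()
    for a in attractors:
        members = np.where(support[a])[0]
        for j in members:
            union(int(a), int(j))
            claimed.add(int(j))
    clusters: dict[int, set[int]] = {}
    for j in range(n):
        root = find(j) if j in claimed else j
        clusters.setdefault(root, set()).add(j)
    return list(clusters.values())


def random_cluster_graph(rng: np.random.Generator, max_nodes: int = 30):
    """A random planted-partition graph: strong within-cluster edges, sparse
    weak bridges.  Returns (node names, edge list, dense adjacency)."""
    n = int(rng.integers(8, max_nodes + 1))
    k = int(rng.integers(2, 5))
    sizes = rng.multinomial(n - k, np.ones(k) / k) + 1
    labels = np.repeat(np.arange(k), sizes)
    nodes = [f"n{i}" for i in range(n)]
    edges = []
    adj = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if labels[i] == labels[j] and rng.random() < 0.9:
                w = float(rng.uniform(0.5, 1.5))
            elif rng.random() < 0.08:
                w = float(rng.uniform(0.05, 0.3))
            else:
                continue
            edges.append((nodes[i], nodes[j], w))
            adj[i, j] = adj[j, i] = w
    return nodes, edges, adj
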