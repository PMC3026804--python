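"""Independent brute-force reference implementations used only by the tests.

Each function is written directly from the defining formula, with explicit
loops and sets, deliberately avoiding the vectorized code paths of the
package under test.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np


def nodf_oracle(mat: np.ndarray) -> float:
    """Direct-definition NODF: paired overlap with strictly decreasing fill."""
    mat = np.asarray(mat)
    r, c = mat.shape

    def line_pairs(lines):
        total = 0.0
        for i, j in combinations(range(len(lines)), 2):
            a, b = set(lines[i]), set(lines[j])
            # order so 'rich' has the larger fill; equal fills contribute 0
            if len(a) == len(b):
                continue
            rich, poor = (a, b) if len(a) > len(b) else (b, a)
            if len(poor) == 0:
                continue
            total += 100.0 * len(rich & poor) / len(poor)
        return total

    rows = [tuple(np.nonzero(mat[i])[0]) for i in range(r)]
    cols = [tuple(np.nonzero(mat[:, k])[0]) for k in range(c)]
    n_pairs = r * (r - 1) / 2 + c * (c - 1) / 2
    return (line_pairs(rows) + line_pairs(cols)) / n_pairs


def projection_oracle(mat: np.ndarray) -> dict:
    """Pairwise shared-partner multiplicities by explicit set intersection."""
    mat = np.asarray(mat)
    partner_sets = [set(np.nonzero(row)[0]) for row in mat]
    out = {}
    for i, j in combinations(range(mat.shape[0]), 2):
        m = len(partner_sets[i] & partner_sets[j])
        if m:
            out[(i, j)] = m
    return out


def degree_oracle(adj: np.ndarray) -> list:
    """Per-node degree by neighbour enumeration."""
    n = adj.shape[0]
    return [sum(1 for j in range(n) if j != i and adj[i, j]) for i in range(n)]


def clustering_oracle(adj: np.ndarray) -> list:
    """Per-node CC1 by counting linked neighbour pairs."""
    n = adj.shape[0]
    out = []
    for i in range(n):
        nbrs = [j for j in range(n) if j != i and adj[i, j]]
        k = len(nbrs)
        if k <= 1:
            out.append(0.0)
            continue
        links = sum(1 for a, b in combinations(nbrs, 2) if adj[a, b])
        out.append(links / (k * (k - 1) / 2))
    return out


def hub_oracle(adj: np.ndarray) -> np.ndarray:
    """Principal eigenvector of the adjacency by dense eigendecomposition."""
    vals, vecs = np.linalg.eigh(adj.astype(float))
    v = vecs[:, np.argmax(vals)]
    v = np.abs(v)
    return v / v.max()


def fs_oracle(adj: np.ndarray, focal: list, target: list) -> float:
    """Mean BFS distance from focal nodes to target nodes via networkx."""
    g = nx.from_numpy_array(adj)
    per_focal = []
    for i in focal:
        lengths = nx.single_source_shortest_path_length(g, i)
        ds = [lengths[j] for j in target if j in lengths and j != i]
        if ds:
            per_focal.append(np.mean(ds))
    return float(np.mean(per_focal))


def anova_oracle(values, labels):
    """Textbook one-way ANOVA decomposition."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in np.unique(labels)]
    grand = values.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = len(groups) - 1, len(values) - len(groups)
    return (ssb / df1) / (ssw / df2), df1, df2
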