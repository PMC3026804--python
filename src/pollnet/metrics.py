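"""Architecture metrics for incidence matrices and unipartite projections.

Nestedness (NODF, paired overlap with strictly decreasing fill, 0-100 scale)
is computed on the binary incidence matrix; degree, connectance and the CC1
clustering coefficient are computed on the simple-graph reduction of a
projection.  Pollinator-side metrics (functional specialization between
functional groups, hub scores) operate on the pollinator projection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .construction import ProjectionGraph

__all__ = [
    "nodf",
    "relative_nestedness",
    "degree_stats",
    "connectance",
    "clustering",
    "functional_specialization",
    "group_functional_specialization",
    "hub_scores",
    "group_hub_degree",
    "MetricsReport",
    "metrics_report",
]


def _nodf_axis(mat: np.ndarray) -> float:
    """Sum of paired-overlap percentages over all row pairs of ``mat``.

    A pair (i, j) contributes only when fills strictly decrease
    (``fill_i > fill_j > 0``), and then 100 * shared / fill_j.
    """
    fills = mat.sum(axis=1)
    shared = (mat @ mat.T).astype(float)
    decreasing = (fills[:, None] > fills[None, :]) & (fills[None, :] > 0)
    denom = np.where(fills > 0, fills, 1)[None, :].astype(float)
    return float((100.0 * shared / denom)[decreasing].sum())


def nodf(presence: np.ndarray) -> float:
    """Nestedness based on overlap and decreasing fill, in [0, 100].

    For every (unordered) pair of rows and pair of columns, the pair
    contributes the percentage of the poorer line's presences that also occur
    in the richer line, but only when the marginal fills strictly decrease;
    equal fills contribute zero.  The score is the mean contribution over all
    ``R(R-1)/2 + C(C-1)/2`` pairs.
    """
    mat = np.asarray(presence)
    if mat.ndim != 2 or mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("nodf requires a matrix with at least 2 rows and 2 columns")
    if not np.isin(mat, (0, 1)).all():
        raise ValueError("presence matrix must be binary")
    if mat.sum() == 0:
        warnings.warn("all-zero matrix: NODF defined as 0", stacklevel=2)
        return 0.0
    r, c = mat.shape
    n_pairs = r * (r - 1) / 2 + c * (c - 1) / 2
    return (_nodf_axis(mat) + _nodf_axis(mat.T)) / n_pairs


def relative_nestedness(observed_nodf: float, null_nodfs: np.ndarray) -> float:
    """(observed - mean(null)) / mean(null) against a null ensemble of NODFs."""
    nulls = np.asarray(null_nodfs, dtype=float)
    if nulls.size < 100:
        warnings.warn(
            f"only {nulls.size} null samples; relative nestedness is unstable",
            stacklevel=2,
        )
    mean_null = nulls.mean()
    if mean_null == 0:
        raise ValueError("null NODF mean is zero; relative nestedness undefined")
    return (observed_nodf - mean_null) / mean_null


def _adjacency(g: ProjectionGraph | np.ndarray) -> np.ndarray:
    if isinstance(g, ProjectionGraph):
        return g.adjacency
    a = np.asarray(g)
    if not np.array_equal(a, a.T) or np.diagonal(a).any():
        raise ValueError("adjacency must be symmetric with zero diagonal")
    return (a >= 1).astype(int)


def degree_stats(g: ProjectionGraph | np.ndarray) -> dict:
    """Degree statistics on the simple reduction.

    Returns mean degree ``k_mean``, per-node degrees, the normalized per-node
    degrees ``k_i/(n-1)`` with their mean and standard error
    (sample SD / sqrt(n)).
    """
    adj = _adjacency(g)
    n = adj.shape[0]
    if n < 2:
        raise ValueError("degree statistics require at least 2 nodes")
    k = adj.sum(axis=1)
    norm = k / (n - 1)
    se = float(norm.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return {
        "degrees": k,
        "k_mean": float(k.mean()),
        "normalized_degrees": norm,
        "normalized_mean": float(norm.mean()),
        "normalized_se": se,
    }


def connectance(g: ProjectionGraph | np.ndarray) -> float:
    """L / (n(n-1)/2): realized fraction of possible links in the simple graph."""
    adj = _adjacency(g)
    n = adj.shape[0]
    if n < 2:
        raise ValueError("connectance requires at least 2 nodes")
    links = adj.sum() / 2
    return float(links / (n * (n - 1) / 2))


def clustering(g: ProjectionGraph | np.ndarray) -> tuple[np.ndarray, float]:
    """CC1 clustering: per-node fraction of linked neighbour pairs, and its mean.

    Nodes with degree <= 1 get C_i = 0.
    """
    adj = _adjacency(g).astype(np.float64)
    k = adj.sum(axis=1)
    # (A^3)_ii = 2 * triangles through i
    tri2 = np.einsum("ij,jk,ki->i", adj, adj, adj)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ci = np.where(denom > 0, tri2 / denom, 0.0)
    return ci, float(ci.mean())


def _group_indices(pg: ProjectionGraph, group) -> np.ndarray:
    idx = np.array(
        [i for i, node in enumerate(pg.nodes) if pg.node_groups.get(node) == group],
        dtype=int,
    )
    if idx.size == 0:
        raise ValueError(f"no nodes belong to functional group {group!r}")
    return idx


def functional_specialization(pg: ProjectionGraph, focal_group, target_group) -> float:
    """Mean topological distance from focal-group species to target-group species.

    For each focal species, the mean unweighted shortest-path length to every
    target-group species is taken; the index is the mean over focal species.
    Unreachable focal-target pairs are excluded with a warning; if every pair
    is unreachable the result is NaN.
    """
    focal = _group_indices(pg, focal_group)
    target = _group_indices(pg, target_group)
    dist = shortest_path(csr_matrix(pg.adjacency), method="D", unweighted=True)
    sub = dist[np.ix_(focal, target)].astype(float)
    if focal_group == target_group:
        # exclude self-distances when comparing a group with itself
        for a, i in enumerate(focal):
            for b, j in enumerate(target):
                if i == j:
                    sub[a, b] = np.inf
    finite = np.isfinite(sub)
    if not finite.all():
        n_bad = int((~finite).sum())
        warnings.warn(
            f"{n_bad} unreachable focal-target pairs excluded from FS",
            stacklevel=2,
        )
    if not finite.any():
        return float("nan")
    per_focal = np.array(
        [row[np.isfinite(row)].mean() for row in sub if np.isfinite(row).any()]
    )
    return float(per_focal.mean())


def group_functional_specialization(pg: ProjectionGraph, focal_group) -> float:
    """Group-level FS: mean FS from the focal group to every other group present."""
    groups = sorted({g for g in pg.node_groups.values() if g is not None})
    others = [g for g in groups if g != focal_group]
    if not others:
        raise ValueError("no other functional groups present")
    vals = []
    for g in others:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fs = functional_specialization(pg, focal_group, g)
        if np.isfinite(fs):
            vals.append(fs)
    return float(np.mean(vals)) if vals else float("nan")


def hub_scores(
    pg: ProjectionGraph | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> np.ndarray:
    """Mutually reinforcing hub scores by power iteration, normalized to max 1.

    On an undirected simple graph hub and authority scores coincide with the
    principal-eigenvector centrality of the adjacency matrix.
    """
    adj = _adjacency(pg).astype(float)
    n = adj.shape[0]
    if n < 2 or adj.sum() == 0:
        raise ValueError("hub scores require a connected component with >= 2 nodes")
    x = np.ones(n)
    shifted = adj + np.eye(n)  # shift breaks the +/-lambda tie on bipartite parts
    for it in range(max_iter):
        y = shifted @ x
        norm = np.linalg.norm(y)
        if norm == 0:  # pragma: no cover - impossible with an edge present
            raise RuntimeError("power iteration collapsed to zero")
        y /= norm
        if np.abs(y - x).max() < tol:
            x = y
            break
        x = y
    else:
        raise RuntimeError(
            f"hub score power iteration did not converge in {max_iter} iterations"
        )
    return x / x.max()


def group_hub_degree(pg: ProjectionGraph, group) -> float:
    """Mean hub score of a functional group's member species."""
    idx = _group_indices(pg, group)
    return float(hub_scores(pg)[idx].mean())


@dataclass
class MetricsReport:
    """Architecture metrics of one population network (one row per population)."""

    n_plants: int
    n_pollinators: int
    nodf: float
    mean_degree: float
    normalized_degree_mean: float
    normalized_degree_se: float
    connectance: float
    clustering_mean: float
    degrees: np.ndarray
    clustering_per_node: np.ndarray

    def to_dict(self) -> dict:
        return {
            "n_plants": self.n_plants,
            "n_pollinators": self.n_pollinators,
            "nodf": self.nodf,
            "mean_degree": self.mean_degree,
            "normalized_degree_mean": self.normalized_degree_mean,
            "normalized_degree_se": self.normalized_degree_se,
            "connectance": self.connectance,
            "clustering_mean": self.clustering_mean,
        }


def metrics_report(inc, g: ProjectionGraph) -> MetricsReport:
    """Compute the full per-population metric battery (incidence + projection)."""
    deg = degree_stats(g)
    ci, cbar = clustering(g)
    return MetricsReport(
        n_plants=len(inc.plants),
        n_pollinators=len(inc.pollinators),
        nodf=nodf(inc.presence),
        mean_degree=deg["k_mean"],
        normalized_degree_mean=deg["normalized_mean"],
        normalized_degree_se=deg["normalized_se"],
        connectance=connectance(g),
        clustering_mean=cbar,
        degrees=deg["degrees"],
        clustering_per_node=ci,
    )
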