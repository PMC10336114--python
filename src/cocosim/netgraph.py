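"""Statistics for protein-protein interaction networks.

Operates on simple undirected labelled graphs (``networkx.Graph``) read
from STRING-style tab-separated edge lists: average node degree, local /
average clustering coefficient, and Markov Cluster Algorithm (MCL)
partitioning of the nodes.

MCL alternates *expansion* (matrix power of the column-stochastic random
walk matrix, spreading flow) with *inflation* (entrywise power followed by
column renormalisation, sharpening it) until the matrix stops changing;
clusters are read off the attractor structure of the limit matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "read_edgelist",
    "average_node_degree",
    "local_clustering",
    "average_clustering",
    "mcl_cluster",
    "MclResult",
    "graph_stats",
]

_HEADERISH = {"node1", "node2", "node", "source", "target", "protein1", "protein2", "from", "to"}


def read_edgelist(path: str | Path, node_list: str | Path | None = None) -> nx.Graph:
    """Read a simple undirected graph from a two-column TSV edge list.

    Duplicate edges (in either orientation) collapse; self-loop rows are
    dropped with a warning; rows with fewer than two fields raise a
    ``ValueError`` naming the line.  Extra columns are ignored.  A header
    row with recognisable column names is tolerated.  ``node_list``
    optionally adds isolated nodes, one label per line.
    """
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 tab-separated fields")
            a, b = fields[0].strip(), fields[1].strip()
            if not a or not b:
                raise ValueError(f"{path}:{lineno}: empty node label")
            if lineno == 1 and a.lower() in _HEADERISH and b.lower() in _HEADERISH:
                continue
            if a == b:
                warnings.warn(f"{path}:{lineno}: dropping self-loop on {a!r}")
                continue
            g.add_edge(a, b)
    if node_list is not None:
        for line in Path(node_list).read_text().splitlines():
            label = line.strip()
            if label and not label.startswith("#"):
                g.add_node(label)
    return g


def average_node_degree(g: nx.Graph) -> float:
    """Average number of interactions per protein: 2|E| / |V|."""
    if g.number_of_nodes() == 0:
        raise ValueError("average degree of an empty graph is undefined")
    return 2 * g.number_of_edges() / g.number_of_nodes()


def local_clustering(g: nx.Graph, node) -> float:
    """Fraction of realised edges among a node's neighbours (0 for degree < 2)."""
    if node not in g:
        raise ValueError(f"node {node!r} not in graph")
    return float(nx.clustering(g, node))


def average_clustering(g: nx.Graph) -> float:
    """Mean local clustering coefficient over all nodes (degree-<2 nodes
    contribute 0)."""
    if g.number_of_nodes() == 0:
        raise ValueError("average clustering of an empty graph is undefined")
    return float(nx.average_clustering(g, count_zeros=True))


@dataclass
class MclResult:
    clusters: list[tuple]
    converged: bool
    n_iter: int

    def as_partition(self) -> dict:
        return {node: i for i, block in enumerate(self.clusters) for node in block}


def mcl_cluster(
    g: nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    tol: float = 1e-8,
    prune: float = 1e-6,
    max_iter: int = 100,
) -> MclResult:
    """Markov Cluster Algorithm partition of the nodes of ``g``.

    Self-loops of weight 1 are added; columns are normalised to a
    column-stochastic matrix; then expansion (power ``expansion``) and
    inflation (entrywise power ``inflation``) alternate, pruning entries
    below ``prune``, until the matrix changes by less than ``tol`` or
    ``max_iter`` is reached (non-convergence returns the current partition
    with ``converged=False`` and a warning).  Clusters are the connected
    overlaps of the attractor rows; each node is assigned exactly once,
    ties going to the lowest-labelled cluster.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty graph")
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes = sorted(g.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for u, v in g.edges():
        m[index[u], index[v]] = 1.0
        m[index[v], index[u]] = 1.0
    np.fill_diagonal(m, 1.0)
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new = np.linalg.matrix_power(m, expansion)
        new = np.power(new, inflation)
        new[new < prune] = 0.0
        colsum = new.sum(axis=0)
        dead = colsum == 0
        if dead.any():  # fully pruned columns fall back to a self-loop
            new[np.argwhere(dead).ravel(), np.argwhere(dead).ravel()] = 1.0
            colsum = new.sum(axis=0)
        new /= colsum
        delta = np.abs(new - m).max()
        m = new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"MCL did not converge within {max_iter} iterations")

    clusters = _clusters_from_limit(m, nodes)
    return MclResult(clusters=clusters, converged=converged, n_iter=it)


def _clusters_from_limit(m: np.ndarray, nodes: list) -> list[tuple]:
    """Read the partition off the MCL limit matrix.

    Attractors are nodes with positive mass on their own diagonal; each
    attractor row spans a cluster; attractor rows sharing any node merge.
    Any node left unassigned joins the cluster of the attractor holding
    the most of its column mass (ties to the lowest-labelled cluster).
    """
    n = len(nodes)
    attractors = [i for i in range(n) if m[i, i] > 0]
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    assignment: dict[int, int] = {}
    for a in attractors:
        support = np.nonzero(m[a, :])[0]
        for j in support:
            if j in assignment:
                union(assignment[j], a)
            else:
                assignment[j] = a
        union(a, a)
    for j in range(n):
        if j not in assignment:
            col = m[:, j]
            if col.max() > 0:
                assignment[j] = int(np.argmax(col))
            else:
                assignment[j] = j  # isolated: its own cluster

    blocks: dict[int, list] = {}
    for j in range(n):
        blocks.setdefault(find(assignment[j]), []).append(nodes[j])
    clusters = [tuple(sorted(b)) for b in blocks.values()]
    clusters.sort(key=lambda c: (-len(c), c))
    return clusters


def graph_stats(g: nx.Graph, mcl: bool = False, inflation: float = 2.0) -> dict:
    """One-stop summary used by the ``net-stats`` CLI subcommand."""
    stats = {
        "nodes": g.number_of_nodes(),
        "edges": g.number_of_edges(),
        "avg_degree": round(average_node_degree(g), 4),
        "avg_clustering": round(average_clustering(g), 4),
    }
    if mcl:
        res = mcl_cluster(g, inflation=inflation)
        stats["clusters"] = [list(c) for c in res.clusters]
        stats["n_clusters"] = len(res.clusters)
        stats["mcl_converged"] = res.converged
    return stats
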