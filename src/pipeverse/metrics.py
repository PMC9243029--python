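"""Nodal graph-metric registry for thresholded connectivity networks.

All metrics operate on the magnitude of edge weights (proportional
thresholding keeps signed weights, but the strongest retained functional
couplings are overwhelmingly positive and path/centrality measures are only
defined for non-negative weights).  Path-based measures use the conventional
length transform ``dist = 1 / |w|``.

Community-dependent measures (participation coefficient, module-degree
z-score, the two gateway coefficients, within-community strength) require a
prior community assignment, mirroring the use of a fixed seven-network
parcellation; the Louvain-based nodal modularity contribution detects its own
communities with a caller-supplied seed so that results are reproducible.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from scipy.sparse.csgraph import dijkstra


def as_graph(W: np.ndarray) -> nx.Graph:
    """Build an undirected graph with ``weight = |w|`` and ``dist = 1/|w|``."""
    A = np.abs(np.asarray(W, dtype=float))
    np.fill_diagonal(A, 0.0)
    G = nx.Graph()
    G.add_nodes_from(range(A.shape[0]))
    i, j = np.nonzero(np.triu(A, k=1))
    G.add_weighted_edges_from(
        (int(a), int(b), float(A[a, b])) for a, b in zip(i, j)
    )
    for _, _, d in G.edges(data=True):
        d["dist"] = 1.0 / d["weight"]
    return G


def _abs_adj(W: np.ndarray) -> np.ndarray:
    A = np.abs(np.asarray(W, dtype=float))
    np.fill_diagonal(A, 0.0)
    return A


def _dict_to_vec(d: dict, n: int) -> np.ndarray:
    return np.array([d.get(i, 0.0) for i in range(n)], dtype=float)


def strength(W, communities=None, seed=0, graph=None):
    return _abs_adj(W).sum(axis=1)


def degree(W, communities=None, seed=0, graph=None):
    return (_abs_adj(W) > 0).sum(axis=1).astype(float)


def betweenness_centrality(W, communities=None, seed=0, graph=None):
    G = graph if graph is not None else as_graph(W)
    return _dict_to_vec(nx.betweenness_centrality(G, weight="dist", normalized=True), len(W))


def eigenvector_centrality(W, communities=None, seed=0, graph=None):
    A = _abs_adj(W)
    if not A.any():
        return np.zeros(len(A))
    vals, vecs = np.linalg.eigh(A)
    v = np.abs(vecs[:, -1])
    return v / np.linalg.norm(v)


def closeness_centrality(W, communities=None, seed=0, graph=None):
    G = graph if graph is not None else as_graph(W)
    return _dict_to_vec(nx.closeness_centrality(G, distance="dist"), len(W))


def pagerank_centrality(W, communities=None, seed=0, graph=None):
    G = graph if graph is not None else as_graph(W)
    return _dict_to_vec(nx.pagerank(G, weight="weight", max_iter=1000), len(W))


def clustering_coefficient(W, communities=None, seed=0, graph=None):
    G = graph if graph is not None else as_graph(W)
    return _dict_to_vec(nx.clustering(G, weight="weight"), len(W))


def local_efficiency(W, communities=None, seed=0, graph=None):
    """Weighted local efficiency: mean inverse shortest-path length within each
    node's neighborhood subgraph (lengths ``1/|w|``); nodes with < 2 neighbors
    score 0."""
    A = _abs_adj(W)
    n = len(A)
    with np.errstate(divide="ignore"):
        dist = np.where(A > 0, 1.0 / A, np.inf)
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(A[i])
        if len(nbrs) < 2:
            continue
        sub = dist[np.ix_(nbrs, nbrs)]
        sp = dijkstra(np.where(np.isinf(sub), 0.0, sub), directed=False)
        iu = np.triu_indices(len(nbrs), k=1)
        with np.errstate(divide="ignore"):
            inv = np.where(np.isfinite(sp[iu]) & (sp[iu] > 0), 1.0 / sp[iu], 0.0)
        out[i] = inv.mean()
    return out


def k_coreness(W, communities=None, seed=0, graph=None):
    G = graph if graph is not None else as_graph(W)
    return _dict_to_vec({k: float(v) for k, v in nx.core_number(G).items()}, len(W))


def subgraph_centrality(W, communities=None, seed=0, graph=None):
    A = _abs_adj(W)
    vals, vecs = np.linalg.eigh(A)
    return (vecs**2) @ np.exp(vals)


def _community_strengths(A: np.ndarray, communities: np.ndarray) -> np.ndarray:
    """Matrix k[i, c] = total |weight| from node i into community c."""
    labels, inverse = np.unique(communities, return_inverse=True)
    k = np.zeros((len(A), len(labels)))
    for c in range(len(labels)):
        k[:, c] = A[:, inverse == c].sum(axis=1)
    return k


def participation_coefficient(W, communities=None, seed=0, graph=None):
    A = _abs_adj(W)
    k = _community_strengths(A, communities)
    tot = k.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 1.0 - ((k / tot[:, None]) ** 2).sum(axis=1)
    p[tot == 0] = 0.0
    return p


def module_degree_zscore(W, communities=None, seed=0, graph=None):
    A = _abs_adj(W)
    communities = np.asarray(communities)
    _, inverse = np.unique(communities, return_inverse=True)
    z = np.zeros(len(A))
    for c in np.unique(inverse):
        members = np.flatnonzero(inverse == c)
        within = A[np.ix_(members, members)].sum(axis=1)
        sd = within.std()
        if sd > 0:
            z[members] = (within - within.mean()) / sd
    return z


def _gateway(W, communities, centrality: np.ndarray) -> np.ndarray:
    """Gateway coefficient: a participation coefficient in which each
    community term is down-weighted by how critical the node is as a gateway,
    g_ic = 1 - (k_ic / K_{m(i),c}) * (cen_i / max cen in m(i)), where
    K_{m(i),c} is the total strength from node i's module into community c."""
    A = _abs_adj(W)
    communities = np.asarray(communities)
    _, inverse = np.unique(communities, return_inverse=True)
    k = _community_strengths(A, communities)
    tot = k.sum(axis=1)
    n, m = k.shape
    module_tot = np.zeros((n, m))
    cen_max = np.zeros(n)
    for c in np.unique(inverse):
        members = inverse == c
        module_tot[members, :] = k[members, :].sum(axis=0)
        cmax = centrality[members].max()
        cen_max[members] = cmax if cmax > 0 else 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        share = np.where(module_tot > 0, k / module_tot, 0.0)
        g = 1.0 - share * (centrality / cen_max)[:, None]
        G = 1.0 - (((k / tot[:, None]) ** 2) * g**2).sum(axis=1)
    G[tot == 0] = 0.0
    return G


def gateway_degree(W, communities=None, seed=0, graph=None):
    return _gateway(W, communities, strength(W))


def gateway_betweenness(W, communities=None, seed=0, graph=None):
    return _gateway(W, communities, betweenness_centrality(W, graph=graph))


def within_community_strength(W, communities=None, seed=0, graph=None):
    A = _abs_adj(W)
    communities = np.asarray(communities)
    _, inverse = np.unique(communities, return_inverse=True)
    out = np.zeros(len(A))
    for c in np.unique(inverse):
        members = np.flatnonzero(inverse == c)
        out[members] = A[np.ix_(members, members)].sum(axis=1)
    return out


def modularity_louvain(W, communities=None, seed=0, graph=None):
    """Nodal contribution to Louvain modularity: q_i = sum over same-community
    neighbors j of (A_ij - k_i k_j / 2m) / 2m.  Community detection is seeded
    by the caller for reproducibility."""
    G = graph if graph is not None else as_graph(W)
    A = _abs_adj(W)
    two_m = A.sum()
    if two_m == 0:
        return np.zeros(len(A))
    parts = nx.community.louvain_communities(G, weight="weight", seed=int(seed))
    member = np.zeros(len(A), dtype=int)
    for c, nodes in enumerate(parts):
        member[list(nodes)] = c
    k = A.sum(axis=1)
    same = member[:, None] == member[None, :]
    np.fill_diagonal(same, False)
    contrib = np.where(same, A - np.outer(k, k) / two_m, 0.0)
    return contrib.sum(axis=1) / two_m


#: default registry of 16 nodal metrics, from simple to higher-level features
NODAL_METRICS = {
    "strength": strength,
    "degree": degree,
    "betweenness_centrality": betweenness_centrality,
    "eigenvector_centrality": eigenvector_centrality,
    "closeness_centrality": closeness_centrality,
    "pagerank_centrality": pagerank_centrality,
    "clustering_coefficient": clustering_coefficient,
    "local_efficiency": local_efficiency,
    "k_coreness": k_coreness,
    "subgraph_centrality": subgraph_centrality,
    "participation_coefficient": participation_coefficient,
    "module_degree_zscore": module_degree_zscore,
    "gateway_degree": gateway_degree,
    "gateway_betweenness": gateway_betweenness,
    "within_community_strength": within_community_strength,
    "modularity_louvain": modularity_louvain,
}

#: metrics that require a prior community assignment
COMMUNITY_METRICS = frozenset(
    {
        "participation_coefficient",
        "module_degree_zscore",
        "gateway_degree",
        "gateway_betweenness",
        "within_community_strength",
    }
)
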