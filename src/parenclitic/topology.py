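"""Weighted-graph topology indices summarizing one parenclitic network.

Twelve indices per graph, in the fixed order of ``TopologyFeatures.ORDER``:
mean / variance / max of edge weights; mean / variance / max of weighted node
degree (deg(v) = sum of incident edge weights); mean / variance of pairwise
shortest-path lengths; graph diameter; Freeman-style graph degree centrality;
graph efficiency (mean inverse distance); and betweenness centrality
(averaged over nodes).

Distance semantics: by default an edge's weight IS its length (the distance
between two nodes is the minimal total edge weight along a path), which makes
strongly deviating edges *long*. The alternative ``length_mode="inverse"``
(length = 1/w) treats strong deviations as short-cuts, which is the reading
under which heavier abnormal edges shrink the graph diameter; both modes are
first-class and are stamped into outputs.

Graph degree centrality follows the normalization

    C_D(G) = H(G) / H_max,   H(G) = sum_i |C_D(v*) - C_D(v_i)|,
    C_D(v) = deg(v) / |V|,   H_max = (|V|-1)(|V|-2),

under which a unit-weight star on n nodes scores 1/n. Note H_max is a
constant, so with weighted degrees this index scales linearly under uniform
edge-weight scaling (unlike betweenness, which is scale-invariant).

Weighted betweenness counts shortest paths with a relative tie tolerance
``eps_path``: two path lengths are considered equal when they differ by less
than ``eps_path`` relatively (exact floating-point equality would make
path counting ill-posed on weighted graphs).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .network import ParencliticNetwork

EPS_PATH = 1e-9  # relative tolerance for shortest-path length ties
EPS_D = 1e-12  # distances below this contribute the capped 1/EPS_D to efficiency


@dataclass(frozen=True)
class TopologyFeatures:
    """The 12-component topology index vector of one network."""

    mean_edge_weight: float
    var_edge_weight: float
    max_edge_weight: float
    mean_degree: float
    var_degree: float
    max_degree: float
    mean_shortest_path: float
    var_shortest_path: float
    diameter: float
    degree_centrality: float
    efficiency: float
    betweenness_centrality: float

    ORDER = (
        "mean_edge_weight",
        "var_edge_weight",
        "max_edge_weight",
        "mean_degree",
        "var_degree",
        "max_degree",
        "mean_shortest_path",
        "var_shortest_path",
        "diameter",
        "degree_centrality",
        "efficiency",
        "betweenness_centrality",
    )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in self.ORDER])

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.ORDER}


assert tuple(f.name for f in fields(TopologyFeatures)) == TopologyFeatures.ORDER


def _length_matrix(net: ParencliticNetwork, length_mode: str) -> np.ndarray:
    """Dense edge-length matrix; +inf marks absent edges and the diagonal."""
    if length_mode not in ("direct", "inverse"):
        raise ValueError(f"unknown length_mode {length_mode!r}")
    w = net.weights
    if (w < 0).any():
        raise ValueError("negative edge weights are not allowed")
    L = np.where(net.edge_mask, w, np.inf)
    if length_mode == "inverse":
        L = np.where(net.edge_mask, 1.0 / np.maximum(w, EPS_D), np.inf)
    np.fill_diagonal(L, np.inf)
    return L


def weighted_degrees(net: ParencliticNetwork) -> np.ndarray:
    """deg(v) = sum of incident edge weights, per node."""
    return np.where(net.edge_mask, net.weights, 0.0).sum(axis=1)


def _sssp_counting(L: np.ndarray, source: int, eps: float):
    """Dijkstra from ``source`` with tolerance-aware shortest-path counting.

    Dense O(n^2) variant (the graphs are near-complete). Returns
    (dist, sigma, preds, order): distances, path counts, boolean predecessor
    matrix (preds[v, u] = u precedes v on some shortest path) and settle order.
    """
    n = L.shape[0]
    dist = np.full(n, np.inf)
    dist[source] = 0.0
    sigma = np.zeros(n)
    sigma[source] = 1.0
    preds = np.zeros((n, n), dtype=bool)
    done = np.zeros(n, dtype=bool)
    order = []
    for _ in range(n):
        u = int(np.where(done, np.inf, dist).argmin())
        if not np.isfinite(dist[u]) or done[u]:
            break
        done[u] = True
        order.append(u)
        alt = dist[u] + L[u]
        cand = ~done & np.isfinite(alt)
        if not cand.any():
            continue
        with np.errstate(invalid="ignore"):
            tol = eps * alt
            better = cand & (alt < dist - tol)
            equal = cand & ~better & (np.abs(alt - dist) <= tol)
        if better.any():
            dist[better] = alt[better]
            sigma[better] = sigma[u]
            preds[better] = False
            preds[better, u] = True
        if equal.any():
            sigma[equal] += sigma[u]
            preds[equal, u] = True
    return dist, sigma, preds, order


def _all_pairs(net: ParencliticNetwork, length_mode: str, eps_path: float):
    """Distance matrix and per-node betweenness in one Dijkstra/Brandes pass."""
    L = _length_matrix(net, length_mode)
    n = L.shape[0]
    D = np.zeros((n, n))
    bc = np.zeros(n)
    for s in range(n):
        dist, sigma, preds, order = _sssp_counting(L, s, eps_path)
        D[s] = dist
        D[s, s] = 0.0
        delta = np.zeros(n)
        for w in reversed(order):
            pw = preds[w]
            if pw.any():
                delta[pw] += sigma[pw] / sigma[w] * (1.0 + delta[w])
        delta[s] = 0.0
        bc += delta
    # each unordered pair contributed from both endpoints as source
    return D, bc / 2.0


def shortest_path_matrix(
    net: ParencliticNetwork, length_mode: str = "direct"
) -> np.ndarray:
    """Pairwise minimal path lengths; unreachable pairs are +inf."""
    D, _ = _all_pairs(net, length_mode, EPS_PATH)
    return D


def betweenness(
    net: ParencliticNetwork, length_mode: str = "direct", eps_path: float = EPS_PATH
) -> np.ndarray:
    """Per-node betweenness: over unordered pairs (i, j), the fraction of
    shortest i-j paths passing through the node as an interior vertex."""
    _, bc = _all_pairs(net, length_mode, eps_path)
    return bc


def _check_connected(D: np.ndarray) -> None:
    if not np.isfinite(D).all():
        n = D.shape[0]
        comp = np.isfinite(D[0])
        raise ValueError(
            f"graph is disconnected ({int(comp.sum())}/{n} nodes reachable from "
            "the first node); restrict to the largest component first"
        )


def diameter(net: ParencliticNetwork, length_mode: str = "direct") -> float:
    """Maximal shortest-path distance between any node pair (connected graphs)."""
    D = shortest_path_matrix(net, length_mode)
    _check_connected(D)
    return float(D.max())


def degree_centrality_graph(net: ParencliticNetwork) -> float:
    """Freeman-style graph degree centralization with weighted degrees."""
    n = net.n_nodes
    if n < 3:
        raise ValueError(f"graph degree centrality needs >= 3 nodes, got {n}")
    cd = weighted_degrees(net) / n
    h = np.abs(cd.max() - cd).sum()
    return float(h / ((n - 1) * (n - 2)))


def efficiency(net: ParencliticNetwork, length_mode: str = "direct") -> float:
    """Mean inverse shortest-path distance over ordered node pairs.

    Infinite distances contribute 0; distances below ``EPS_D`` contribute the
    capped value 1/EPS_D (only reachable for control-identical samples).
    """
    D = shortest_path_matrix(net, length_mode)
    return _efficiency_from_distances(D)


def _efficiency_from_distances(D: np.ndarray) -> float:
    n = D.shape[0]
    off = ~np.eye(n, dtype=bool)
    d = D[off]
    inv = np.zeros_like(d)
    finite = np.isfinite(d)
    tiny = finite & (d < EPS_D)
    inv[finite & ~tiny] = 1.0 / d[finite & ~tiny]
    inv[tiny] = 1.0 / EPS_D
    return float(inv.sum() / (n * (n - 1)))


def extract_features(
    net: ParencliticNetwork,
    length_mode: str = "direct",
    largest_component: bool = False,
) -> TopologyFeatures:
    """Assemble the 12-index topology feature vector of one network.

    Edge statistics run over the present edges; degree statistics over all
    nodes; path statistics over unordered node pairs. "Variance" is the
    sample variance (divisor n-1). Disconnected graphs are an error unless
    ``largest_component`` restricts the path-based metrics to the largest
    connected component.
    """
    w, mask = net.condensed_weights()
    ew = w[mask]
    if ew.size == 0:
        raise ValueError("network has no edges")
    deg = weighted_degrees(net)
    D, bc = _all_pairs(net, length_mode, EPS_PATH)
    if largest_component and not np.isfinite(D).all():
        keep = np.isfinite(D).sum(axis=1).argmax()
        comp = np.isfinite(D[keep])
        D = D[np.ix_(comp, comp)]
    _check_connected(D)
    iu = np.triu_indices(D.shape[0], 1)
    paths = D[iu]
    cd = deg / net.n_nodes
    n = net.n_nodes
    if n < 3:
        raise ValueError("feature extraction needs >= 3 nodes")
    h = np.abs(cd.max() - cd).sum()
    return TopologyFeatures(
        mean_edge_weight=float(ew.mean()),
        var_edge_weight=float(ew.var(ddof=1)) if ew.size > 1 else 0.0,
        max_edge_weight=float(ew.max()),
        mean_degree=float(deg.mean()),
        var_degree=float(deg.var(ddof=1)),
        max_degree=float(deg.max()),
        mean_shortest_path=float(paths.mean()),
        var_shortest_path=float(paths.var(ddof=1)) if paths.size > 1 else 0.0,
        diameter=float(paths.max()),
        degree_centrality=float(h / ((n - 1) * (n - 2))),
        efficiency=_efficiency_from_distances(D),
        betweenness_centrality=float(bc.mean()),
    )
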