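"""Independent brute-force oracles used by the topology tests.

Everything here deliberately avoids the package's Dijkstra/Brandes machinery:
distances and betweenness come from exhaustive enumeration of simple paths,
and the graph-level indices are computed by direct transcription of their
defining formulas.
"""

from __future__ import annotations

import numpy as np

from parenclitic.network import ParencliticNetwork


def random_network(rng, n_nodes=None, edge_prob=0.85, w_lo=0.1, w_hi=1.0):
    """Random connected weighted graph wrapped as a ParencliticNetwork."""
    while True:
        n = int(n_nodes if n_nodes is not None else rng.integers(4, 9))
        iu = np.triu_indices(n, 1)
        keep = rng.random(len(iu[0])) < edge_prob
        w = rng.uniform(w_lo, w_hi, size=len(iu[0]))
        W = np.zeros((n, n))
        W[iu] = np.where(keep, w, 0.0)
        W += W.T
        mask = np.zeros((n, n), dtype=bool)
        mask[iu] = keep
        mask |= mask.T
        if _connected(mask):
            return ParencliticNetwork(
                "toy", [f"g{i}" for i in range(n)], W, "regression", mask
            )


def _connected(mask) -> bool:
    n = mask.shape[0]
    seen = {0}
    frontier = [0]
    while frontier:
        u = frontier.pop()
        for v in np.flatnonzero(mask[u]):
            if v not in seen:
                seen.add(int(v))
                frontier.append(int(v))
    return len(seen) == n


def brute_force_paths(net: ParencliticNetwork, eps: float = 1e-9):
    """All-pairs shortest distances and betweenness via exhaustive simple-path
    enumeration, with the same relative tie tolerance as the implementation."""
    n = net.n_nodes
    W = net.weights
    adj = [list(np.flatnonzero(net.edge_mask[u])) for u in range(n)]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    bc = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            lengths, interiors = [], []
            stack = [(i, (i,), 0.0)]
            while stack:
                u, path, ln = stack.pop()
                if u == j:
                    lengths.append(ln)
                    interiors.append(path[1:-1])
                    continue
                for v in adj[u]:
                    if v not in path:
                        stack.append((v, path + (v,), ln + W[u, v]))
            if not lengths:
                continue
            best = min(lengths)
            D[i, j] = D[j, i] = best
            tol = eps * max(best, 1e-300)
            shortest = [it for ln, it in zip(lengths, interiors) if ln <= best + tol]
            sigma = len(shortest)
            for it in shortest:
                for k in it:
                    bc[k] += 1.0 / sigma
    return D, bc


def transcribe_degree_centrality(net: ParencliticNetwork) -> float:
    """Direct transcription of the graph degree-centralization formula."""
    n = net.n_nodes
    deg = np.where(net.edge_mask, net.weights, 0.0).sum(axis=1)
    cd = deg / n
    v_star = cd.argmax()
    h = sum(abs(cd[v_star] - cd[i]) for i in range(n))
    return h / ((n - 1) * (n - 2))


def transcribe_efficiency(D: np.ndarray) -> float:
    """Mean inverse distance over ordered pairs, from oracle distances."""
    n = D.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(D[i, j]) and D[i, j] > 0:
                total += 1.0 / D[i, j]
    return total / (n * (n - 1))
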