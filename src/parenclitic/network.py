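"""Per-sample parenclitic graph construction and export.

A parenclitic network is one subject's complete weighted graph over the gene
panel: nodes are genes, the weight of edge (i, j) measures how far that
subject's pair of methylation levels deviates from the control-group model of
the pair. With the regression kernel the weight is the absolute regression
residual in units of the control residual standard deviation,

    w_ij = |x_j - (alpha_ij + beta_ij * x_i)| / sigma_ij,

and with the Mahalanobis kernel it is the squared Mahalanobis distance of
(x_i, x_j) from the control cloud,

    w_ij = (x - mu)^T S^{-1} (x - mu).

Pairs flagged degenerate by the control model carry no edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .control_model import ControlModel, PairMahalanobis, PairRegression
from .matrix import MethylationMatrix


@dataclass
class ParencliticNetwork:
    """One sample's complete weighted graph over the gene panel.

    ``weights`` is a symmetric G x G nonnegative matrix with zero diagonal;
    ``edge_mask`` marks pairs that carry an edge (False for pairs dropped as
    degenerate). A zero weight on a masked-in edge is a genuine zero-length
    edge (sample exactly at the control reference).
    """

    sample_id: str
    gene_ids: list[str]
    weights: np.ndarray
    kernel: str
    edge_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        g = len(self.gene_ids)
        if w.shape != (g, g):
            raise ValueError(f"weight matrix shape {w.shape} != ({g},{g})")
        if not np.allclose(w, w.T, rtol=0, atol=0):
            raise ValueError("weight matrix must be exactly symmetric")
        if np.diag(w).any():
            raise ValueError("diagonal must be zero")
        if not np.isfinite(w).all() or (w < 0).any():
            raise ValueError("weights must be finite and nonnegative")
        self.weights = w
        if self.edge_mask is None:
            m = np.ones((g, g), dtype=bool)
            np.fill_diagonal(m, False)
            self.edge_mask = m
        else:
            m = np.asarray(self.edge_mask, dtype=bool)
            if m.shape != (g, g) or (m != m.T).any() or np.diag(m).any():
                raise ValueError("edge_mask must be symmetric with empty diagonal")
            self.edge_mask = m

    @property
    def n_nodes(self) -> int:
        return len(self.gene_ids)

    def condensed_weights(self) -> tuple[np.ndarray, np.ndarray]:
        """(weights, mask) over the G(G-1)/2 pairs in i<j order."""
        ii, jj = np.triu_indices(self.n_nodes, 1)
        return self.weights[ii, jj], self.edge_mask[ii, jj]

    def edges(self):
        """Iterate (gene_i, gene_j, weight) over present edges, i<j order."""
        ii, jj = np.triu_indices(self.n_nodes, 1)
        for a, b in zip(ii, jj):
            if self.edge_mask[a, b]:
                yield self.gene_ids[a], self.gene_ids[b], float(self.weights[a, b])


# -- edge weight kernels ---------------------------------------------------


def edge_weight_regression(x_i: float, x_j: float, params: PairRegression) -> float:
    """|residual| / sigma deviation of (x_i, x_j) from the pair's OLS line."""
    if not params.sigma > 0:
        raise ValueError(
            f"sigma={params.sigma} is not positive; degenerate pair cannot be weighted"
        )
    return abs(x_j - (params.alpha + params.beta * x_i)) / params.sigma


def edge_weight_mahalanobis(x, params: PairMahalanobis, sqrt: bool = False) -> float:
    """Squared Mahalanobis distance of the 2-vector ``x`` from the control
    cloud (optionally its square root)."""
    S = np.asarray(params.S, dtype=float)
    det = S[0, 0] * S[1, 1] - S[0, 1] * S[1, 0]
    if det <= 0:
        raise ValueError(f"singular covariance (det={det}); pair cannot be weighted")
    d = np.asarray(x, dtype=float) - np.asarray(params.mu, dtype=float)
    w = (S[1, 1] * d[0] ** 2 - 2 * S[0, 1] * d[0] * d[1] + S[0, 0] * d[1] ** 2) / det
    w = max(w, 0.0)
    return float(np.sqrt(w)) if sqrt else float(w)


def _condensed_weights(x: np.ndarray, model: ControlModel) -> np.ndarray:
    ii, jj = model.pair_arrays()
    ok = ~model.degenerate
    w = np.zeros(model.n_pairs)
    if model.kernel == "regression":
        a = model.params["alpha"]
        b = model.params["beta"]
        s = model.params["sigma"]
        w[ok] = np.abs(x[jj[ok]] - (a[ok] + b[ok] * x[ii[ok]])) / s[ok]
    else:
        dx = x[ii] - model.params["mu_i"]
        dy = x[jj] - model.params["mu_j"]
        s_ii, s_ij, s_jj = (model.params[k] for k in ("s_ii", "s_ij", "s_jj"))
        det = s_ii * s_jj - s_ij**2
        if (det[ok] <= 0).any():
            bad = np.flatnonzero(ok & (det <= 0))[0]
            gi, gj = ii[bad], jj[bad]
            raise ValueError(
                f"singular covariance for pair ({model.gene_ids[gi]}, "
                f"{model.gene_ids[gj]}); refit with ridge > 0"
            )
        q = (s_jj * dx**2 - 2 * s_ij * dx * dy + s_ii * dy**2) / det
        q = np.clip(q, 0.0, None)
        if model.sqrt_distance:
            q = np.sqrt(q)
        w[ok] = q[ok]
    return w


def build_network(
    matrix: MethylationMatrix,
    sample_id: str,
    model: ControlModel,
    allow_control: bool = False,
) -> ParencliticNetwork:
    """Build one sample's complete weighted graph against the control model.

    The matrix must contain every gene of the model panel (extra genes are
    ignored; missing genes are an error). Building a network for one of the
    model's own control samples is refused unless ``allow_control``.
    """
    missing = [g for g in model.gene_ids if g not in matrix.values.index]
    if missing:
        raise ValueError(f"gene panel mismatch; matrix lacks genes {missing[:10]}")
    if sample_id in model.control_ids and not allow_control:
        raise ValueError(
            f"sample {sample_id!r} is in the model's control group; "
            "pass allow_control=True to override"
        )
    x = matrix.values.loc[model.gene_ids, sample_id].to_numpy(dtype=float)
    return build_network_from_vector(x, model, sample_id)


def build_network_from_vector(
    x: np.ndarray, model: ControlModel, sample_id: str = ""
) -> ParencliticNetwork:
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_genes,):
        raise ValueError(f"sample vector length {x.shape} != panel size {model.n_genes}")
    g = model.n_genes
    ii, jj = model.pair_arrays()
    w = _condensed_weights(x, model)
    W = np.zeros((g, g))
    W[ii, jj] = w
    W += W.T
    mask = np.zeros((g, g), dtype=bool)
    ok = ~model.degenerate
    mask[ii[ok], jj[ok]] = True
    mask |= mask.T
    return ParencliticNetwork(
        sample_id=sample_id,
        gene_ids=list(model.gene_ids),
        weights=W,
        kernel=model.kernel,
        edge_mask=mask,
        meta={"n_dropped_pairs": int(model.degenerate.sum())},
    )


def stream_pair_weights(x: np.ndarray, model: ControlModel, chunk_size: int = 1_000_000):
    """Yield (i_idx, j_idx, weights) condensed chunks without a dense matrix.

    Intended for very large panels where the G x G matrix does not fit in
    memory; edge-list export and top-k selection can consume the stream.
    Degenerate pairs are omitted.
    """
    w = _condensed_weights(np.asarray(x, dtype=float), model)
    ii, jj = model.pair_arrays()
    ok = ~model.degenerate
    ii, jj, w = ii[ok], jj[ok], w[ok]
    for start in range(0, len(w), chunk_size):
        sl = slice(start, start + chunk_size)
        yield ii[sl], jj[sl], w[sl]


def top_edges_subgraph(net: ParencliticNetwork, k: int):
    """The k largest-weight edges and their incident nodes.

    Ties at the boundary are broken by lexicographic gene-pair order (the
    lexicographically smaller pair is included first). Returns
    ``(edges, nodes)`` with edges as (gene_i, gene_j, weight) tuples sorted by
    descending weight then pair order.
    """
    all_edges = list(net.edges())
    if not (1 <= k <= len(all_edges)):
        raise ValueError(f"k={k} out of range [1, {len(all_edges)}]")
    all_edges.sort(key=lambda e: (-e[2], e[0], e[1]))
    chosen = all_edges[:k]
    nodes = sorted({g for gi, gj, _ in chosen for g in (gi, gj)})
    return chosen, nodes


# -- export ----------------------------------------------------------------


def write_edgelist_tsv(net_or_edges, path) -> None:
    """3-column weighted edge list (gene_i, gene_j, weight)."""
    edges = net_or_edges.edges() if isinstance(net_or_edges, ParencliticNetwork) else net_or_edges
    with open(path, "w") as fh:
        fh.write("gene_i\tgene_j\tweight\n")
        for gi, gj, w in edges:
            fh.write(f"{gi}\t{gj}\t{w!r}\n")


def to_networkx(net: ParencliticNetwork):
    import networkx as nx

    G = nx.Graph(sample_id=net.sample_id, kernel=net.kernel)
    G.add_nodes_from(net.gene_ids)
    G.add_weighted_edges_from(net.edges())
    return G


def write_graphml(net: ParencliticNetwork, path) -> None:
    import networkx as nx

    nx.write_graphml(to_networkx(net), path)
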