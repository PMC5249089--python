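"""Control-group pairwise reference models for parenclitic edge weighting.

For every unordered gene pair (i < j) the control samples define either

* a **regression** model  m_j = alpha + beta * m_i  fitted by ordinary least
  squares, with ``sigma`` the standard deviation of the control residuals, or
* a **mahalanobis** model: the control mean vector ``mu`` and 2x2 sample
  covariance ``S`` of (m_i, m_j).

Edge weights for a new sample measure its deviation from these references
(see :mod:`parenclitic.network`). The regression orientation is fixed:
the lower-indexed gene of the pair is the predictor; this is recorded in the
model so weights are reproducible.

Per-pair parameters are stored as condensed vectors over the G(G-1)/2 pairs
in upper-triangle (i < j) order, the same order as
``numpy.triu_indices(G, 1)``.
"""

from __future__ import annotations

import io
import json
import logging
import zipfile
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .matrix import MethylationMatrix

log = logging.getLogger(__name__)

FORMAT_VERSION = 1
_SIGMA_TINY = 1e-15  # below this, Eq-style |residual|/sigma is undefined
_DET_REL_TOL = 1e-12  # covariance treated as singular below this relative det


class PairRegression(NamedTuple):
    alpha: float
    beta: float
    sigma: float


class PairMahalanobis(NamedTuple):
    mu: np.ndarray  # (2,)
    S: np.ndarray  # (2, 2)


@dataclass
class ControlModel:
    """Fitted per-pair control model over a gene panel.

    ``params`` holds condensed per-pair arrays:

    * regression kernel: ``alpha``, ``beta``, ``sigma`` (predictor = lower
      gene index, response = higher);
    * mahalanobis kernel: ``mu_i``, ``mu_j``, ``s_ii``, ``s_ij``, ``s_jj``.

    ``degenerate`` flags pairs whose weight is undefined (sigma == 0, or a
    singular covariance when no ridge was applied); the default policy drops
    those edges from the per-sample graphs.
    """

    kernel: str
    gene_ids: list[str]
    control_ids: list[str]
    params: dict[str, np.ndarray]
    degenerate: np.ndarray
    ridge: float = 0.0
    sqrt_distance: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kernel not in ("regression", "mahalanobis"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        npairs = self.n_pairs
        for name, arr in self.params.items():
            if arr.shape != (npairs,):
                raise ValueError(f"param {name!r} has shape {arr.shape}, expected ({npairs},)")
        if self.degenerate.shape != (npairs,):
            raise ValueError("degenerate mask length mismatch")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_pairs(self) -> int:
        g = self.n_genes
        return g * (g - 1) // 2

    def pair_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Condensed (i, j) index arrays, i < j, matching the param order."""
        return np.triu_indices(self.n_genes, 1)

    def pair_index(self, i: int, j: int) -> int:
        if i == j:
            raise ValueError("no self-pairs")
        if i > j:
            i, j = j, i
        g = self.n_genes
        return i * (2 * g - i - 1) // 2 + (j - i - 1)

    def pair_params(self, i: int, j: int):
        """Parameters of the unordered pair (i, j); symmetric in i and j."""
        p = self.pair_index(i, j)
        if self.kernel == "regression":
            return PairRegression(
                float(self.params["alpha"][p]),
                float(self.params["beta"][p]),
                float(self.params["sigma"][p]),
            )
        mu = np.array([self.params["mu_i"][p], self.params["mu_j"][p]])
        S = np.array(
            [
                [self.params["s_ii"][p], self.params["s_ij"][p]],
                [self.params["s_ij"][p], self.params["s_jj"][p]],
            ]
        )
        return PairMahalanobis(mu, S)


def _control_values(controls) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(controls, MethylationMatrix):
        return (
            controls.values.to_numpy(dtype=float),
            controls.gene_ids,
            controls.sample_ids,
        )
    arr = np.asarray(controls.to_numpy(dtype=float) if hasattr(controls, "to_numpy") else controls, dtype=float)
    genes = list(getattr(controls, "index", range(arr.shape[0])))
    samples = list(getattr(controls, "columns", range(arr.shape[1])))
    return arr, [str(g) for g in genes], [str(s) for s in samples]


def fit_regression(controls, strict: bool = False) -> ControlModel:
    """OLS reference model per gene pair from the control samples.

    For each unordered pair (i < j) the higher-indexed gene is regressed on
    the lower-indexed one over the control columns; ``sigma`` is the sample
    standard deviation (divisor n-1) of the residuals. Pairs with a constant
    predictor, or with sigma == 0 (exact collinearity), are flagged
    degenerate; with ``strict`` they raise instead.
    """
    X, genes, samples = _control_values(controls)
    g, n = X.shape
    if n < 3:
        raise ValueError(f"need >= 3 control samples, got {n}")
    C = np.cov(X, ddof=1)
    C = np.atleast_2d(C)
    mean = X.mean(axis=1)
    ii, jj = np.triu_indices(g, 1)
    var_i = C[ii, ii]
    cov_ij = C[ii, jj]
    var_j = C[jj, jj]
    const_pred = var_i <= _SIGMA_TINY
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(const_pred, np.nan, cov_ij / var_i)
        alpha = mean[jj] - beta * mean[ii]
        resid_var = var_j - np.where(const_pred, np.nan, cov_ij**2 / var_i)
    sigma = np.sqrt(np.clip(resid_var, 0.0, None))
    degenerate = const_pred | ~np.isfinite(sigma) | (sigma <= _SIGMA_TINY)
    if degenerate.any():
        pairs = [(genes[a], genes[b]) for a, b in zip(ii[degenerate], jj[degenerate])]
        if strict:
            raise ValueError(f"degenerate regression pairs: {pairs[:10]}")
        log.warning("%d degenerate regression pairs dropped, e.g. %s", len(pairs), pairs[:3])
    return ControlModel(
        kernel="regression",
        gene_ids=genes,
        control_ids=samples,
        params={"alpha": alpha, "beta": beta, "sigma": sigma},
        degenerate=degenerate,
        meta={"orientation": "predictor=lower_gene_index", "n_controls": n},
    )


def fit_mahalanobis(controls, ridge: float = 1e-8) -> ControlModel:
    """Mean and 2x2 sample covariance per gene pair from the controls.

    Covariances use divisor n-1. If a pair's covariance determinant is below a
    relative tolerance (constant or exactly collinear genes), ``ridge * I`` is
    added to its diagonal; with ``ridge=0`` such pairs are flagged degenerate
    and weighting them is an error.
    """
    if ridge < 0:
        raise ValueError("ridge must be nonnegative")
    X, genes, samples = _control_values(controls)
    g, n = X.shape
    if n < 3:
        raise ValueError(f"need >= 3 control samples, got {n}")
    C = np.atleast_2d(np.cov(X, ddof=1))
    mean = X.mean(axis=1)
    ii, jj = np.triu_indices(g, 1)
    s_ii = C[ii, ii].copy()
    s_jj = C[jj, jj].copy()
    s_ij = C[ii, jj].copy()
    det = s_ii * s_jj - s_ij**2
    singular = det <= _DET_REL_TOL * np.maximum(s_ii * s_jj, _SIGMA_TINY)
    if ridge > 0:
        s_ii[singular] += ridge
        s_jj[singular] += ridge
        degenerate = np.zeros(len(ii), dtype=bool)
    else:
        degenerate = singular
    return ControlModel(
        kernel="mahalanobis",
        gene_ids=genes,
        control_ids=samples,
        params={"mu_i": mean[ii], "mu_j": mean[jj], "s_ii": s_ii, "s_ij": s_ij, "s_jj": s_jj},
        degenerate=degenerate,
        ridge=ridge,
        meta={"n_controls": n, "n_ridged": int(singular.sum())},
    )


# -- serialization ---------------------------------------------------------


def save_model(model: ControlModel, path) -> None:
    """Write the model as an .npz archive with an embedded JSON header."""
    header = {
        "format": "parenclitic-control-model",
        "version": FORMAT_VERSION,
        "kernel": model.kernel,
        "gene_ids": model.gene_ids,
        "control_ids": model.control_ids,
        "ridge": model.ridge,
        "sqrt_distance": model.sqrt_distance,
        "meta": model.meta,
        "param_names": sorted(model.params),
    }
    arrays = {f"param_{k}": v for k, v in model.params.items()}
    arrays["degenerate"] = model.degenerate
    with open(path, "wb") as fh:
        np.savez(fh, header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_model(path) -> ControlModel:
    try:
        with np.load(path, allow_pickle=False) as npz:
            header = json.loads(bytes(npz["header"]).decode())
            if header.get("format") != "parenclitic-control-model":
                raise ValueError(f"{path}: not a control-model file")
            if header.get("version") != FORMAT_VERSION:
                raise ValueError(
                    f"{path}: format version {header.get('version')} unsupported "
                    f"(expected {FORMAT_VERSION})"
                )
            params = {k: npz[f"param_{k}"] for k in header["param_names"]}
            degenerate = npz["degenerate"]
    except (OSError, ValueError, KeyError, json.JSONDecodeError, zipfile.BadZipFile) as exc:
        if isinstance(exc, ValueError) and "control-model" in str(exc):
            raise
        raise ValueError(f"{path}: corrupted or unreadable model file ({exc})") from exc
    return ControlModel(
        kernel=header["kernel"],
        gene_ids=list(header["gene_ids"]),
        control_ids=list(header["control_ids"]),
        params=params,
        degenerate=degenerate,
        ridge=header["ridge"],
        sqrt_distance=header["sqrt_distance"],
        meta=header["meta"],
    )


def export_model_tsv(model: ControlModel, path) -> None:
    """Flat per-pair TSV export (gene_i, gene_j, params..., degenerate)."""
    ii, jj = model.pair_arrays()
    names = sorted(model.params)
    buf = io.StringIO()
    buf.write("gene_i\tgene_j\t" + "\t".join(names) + "\tdegenerate\n")
    for p, (a, b) in enumerate(zip(ii, jj)):
        vals = "\t".join(repr(float(model.params[k][p])) for k in names)
        buf.write(
            f"{model.gene_ids[a]}\t{model.gene_ids[b]}\t{vals}\t{int(model.degenerate[p])}\n"
        )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
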