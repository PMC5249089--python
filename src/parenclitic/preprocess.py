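"""Probe-level preprocessing: coverage filtering, KNN imputation, gene averaging.

Turns a probe x sample methylation matrix (with optional detection p-values)
into the dense gene-level [0, 1] matrix the network stages consume. The rules
mirror standard 450k-array practice: drop blacklisted / unannotated probes and
probes observed in fewer than a minimum fraction of samples, replace entries
whose detection p-value exceeds a threshold by k-nearest-neighbour imputation
over probe rows, then characterise each gene by the mean of its probes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import MethylationMatrix

log = logging.getLogger(__name__)


@dataclass
class ProbeMatrix:
    """Probe x sample methylation values, optionally with detection p-values.

    ``values`` may contain NaN (missing observations). ``detection_p``, when
    present, must share shape and index order with ``values``.
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("duplicate probe ids")
        if not self.values.columns.is_unique:
            raise ValueError("duplicate sample ids")
        dp = self.detection_p
        if dp is not None:
            if dp.shape != self.values.shape:
                raise ValueError(
                    f"detection_p shape {dp.shape} != values shape {self.values.shape}"
                )
            if list(dp.index) != list(self.values.index) or list(dp.columns) != list(
                self.values.columns
            ):
                raise ValueError("detection_p index/columns differ from values")
            arr = dp.to_numpy(dtype=float)
            if np.nanmin(arr) < 0 or np.nanmax(arr) > 1:
                raise ValueError("detection p-values must lie in [0,1]")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ProbeGeneMap:
    """Probe -> gene annotation; multiple probes per gene allowed."""

    table: pd.DataFrame  # columns: probe_id, gene_id

    def __post_init__(self) -> None:
        t = self.table
        if list(t.columns[:2]) != ["probe_id", "gene_id"]:
            t = t.iloc[:, :2].set_axis(["probe_id", "gene_id"], axis=1)
        t = t.dropna()
        t = t[t["gene_id"].astype(str).str.len() > 0]
        if t["probe_id"].duplicated().any():
            dup = t.loc[t["probe_id"].duplicated(), "probe_id"].tolist()
            raise ValueError(f"probe mapped to more than one gene: {dup[:5]}")
        self.table = t.reset_index(drop=True)

    @property
    def probe_to_gene(self) -> pd.Series:
        return self.table.set_index("probe_id")["gene_id"]


def filter_probes(
    pm: ProbeMatrix,
    pmap: ProbeGeneMap,
    coverage_min: float = 0.95,
    blacklist=(),
) -> ProbeMatrix:
    """Keep probes that are annotated, not blacklisted and well covered.

    A probe survives iff it (a) is absent from ``blacklist``, (b) appears in
    the probe->gene map, and (c) has a non-missing value in at least
    ``coverage_min`` of the samples. Sample order is preserved.
    """
    if not (0 < coverage_min <= 1):
        raise ValueError(f"coverage_min must lie in (0,1], got {coverage_min}")
    probes = pm.values.index
    black = probes.isin(set(blacklist))
    mapped = probes.isin(set(pmap.table["probe_id"]))
    frac = pm.values.notna().mean(axis=1).to_numpy()
    covered = frac >= coverage_min
    keep = ~black & mapped & covered
    if not keep.any():
        counts = {
            "blacklisted": int(black.sum()),
            "unannotated": int((~mapped).sum()),
            f"coverage<{coverage_min}": int((~covered).sum()),
        }
        binding = max(counts, key=counts.get)
        raise ValueError(
            f"no probe survives filtering (binding constraint: {binding}; "
            f"removal counts {counts})"
        )
    dp = None if pm.detection_p is None else pm.detection_p.loc[keep]
    return ProbeMatrix(pm.values.loc[keep].copy(), dp, dict(pm.meta))


def _knn_impute_entries(
    values: np.ndarray, replace: np.ndarray, k: int, probe_ids
) -> np.ndarray:
    """Replace ``replace``-masked entries of ``values`` by the mean of the k
    nearest probe rows.

    Distances are plain Euclidean over the samples where both rows are
    observed (non-NaN); detection-failed values are unreliable but observed,
    so they still participate in distances and neighbour means — which keeps
    the rule well defined even when every entry of a row is flagged.
    """
    out = values.copy()
    observed = ~np.isnan(values)
    for r in np.flatnonzero(replace.any(axis=1)):
        diffs = values - values[r]
        shared = observed & observed[r]  # columns observed in both rows
        sq = np.where(shared, diffs * diffs, 0.0).sum(axis=1)
        dist = np.sqrt(sq)
        dist[r] = np.inf
        dist[shared.sum(axis=1) == 0] = np.inf  # no co-observation
        for s in np.flatnonzero(replace[r]):
            cand = np.flatnonzero(observed[:, s] & np.isfinite(dist))
            cand = cand[cand != r]
            if cand.size < k:
                raise ValueError(
                    f"probe {probe_ids[r]!r}: only {cand.size} probes share valid "
                    f"observations at sample index {s}; need k={k} neighbours"
                )
            nearest = cand[np.argsort(dist[cand], kind="stable")[:k]]
            out[r, s] = values[nearest, s].mean()
    return out


def impute_detection_failures(
    pm: ProbeMatrix,
    p_max: float = 0.05,
    k: int = 5,
    impute_missing: bool = True,
) -> ProbeMatrix:
    """KNN-impute entries whose detection p-value exceeds ``p_max``.

    Distance between probe rows is plain Euclidean over the samples observed
    (non-missing) in both rows; the imputed value is the unweighted mean of
    the k nearest rows' values at that sample. With ``impute_missing``
    (default) remaining NaN entries are filled by the same rule, so the
    output is dense. Entries that are neither flagged nor missing pass
    through unchanged.
    """
    if pm.detection_p is None:
        raise ValueError("detection_p matrix required for imputation")
    if k < 1 or k > pm.values.shape[0] - 1:
        raise ValueError(f"k={k} out of range for {pm.values.shape[0]} probes")
    values = pm.values.to_numpy(dtype=float)
    flagged = pm.detection_p.to_numpy(dtype=float) > p_max
    replace = flagged | (np.isnan(values) if impute_missing else False)
    if not replace.any():
        return ProbeMatrix(pm.values.copy(), pm.detection_p.copy(), dict(pm.meta))
    imputed = _knn_impute_entries(values, replace, k, pm.probe_ids)
    vals = pd.DataFrame(imputed, index=pm.values.index, columns=pm.values.columns)
    dp = pm.detection_p.mask(flagged, 0.0)
    return ProbeMatrix(vals, dp, dict(pm.meta))


def aggregate_to_genes(
    pm: ProbeMatrix,
    pmap: ProbeGeneMap,
    rescale: str = "global",
) -> MethylationMatrix:
    """Average probes within each gene and rescale into [0, 1].

    Each gene's level per sample is the arithmetic mean of its probes' values.
    ``rescale``: ``"global"`` min-max rescales the whole matrix only if values
    fall outside [0, 1] (in-range data pass through untouched, preserving
    relative gene differences); ``"per_gene"`` min-max rescales each gene row;
    ``"none"`` requires in-range input. Gene order is lexicographic.
    """
    if rescale not in ("global", "per_gene", "none"):
        raise ValueError(f"unknown rescale mode {rescale!r}")
    p2g = pmap.probe_to_gene
    unmapped = [p for p in pm.probe_ids if p not in p2g.index]
    if unmapped:
        raise ValueError(f"probes without gene annotation: {unmapped[:5]}")
    if pm.values.isna().any().any():
        raise ValueError("probe matrix still has missing values; impute first")
    genes = p2g.loc[pm.values.index]
    agg = pm.values.groupby(genes.to_numpy()).mean()
    agg = agg.sort_index()
    arr = agg.to_numpy(dtype=float)
    lo, hi = arr.min(), arr.max()
    applied = "none"
    if rescale == "per_gene":
        rlo = arr.min(axis=1, keepdims=True)
        rhi = arr.max(axis=1, keepdims=True)
        span = np.where(rhi > rlo, rhi - rlo, 1.0)
        arr = (arr - rlo) / span
        applied = "per_gene"
    elif rescale == "global" and (lo < 0 or hi > 1):
        arr = (arr - lo) / (hi - lo if hi > lo else 1.0)
        applied = "global"
    elif rescale == "none" and (lo < 0 or hi > 1):
        raise ValueError("values outside [0,1] and rescale='none'")
    out = pd.DataFrame(arr, index=agg.index, columns=agg.columns)
    meta = dict(pm.meta)
    meta["rescale"] = applied
    meta["rescale_order"] = "after_gene_averaging"
    return MethylationMatrix(out, None, meta)
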