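"""Gene-level methylation matrix container.

The pipeline's substrate is a genes x samples matrix of methylation levels
(beta-value-like fractions in [0, 1]) together with a per-sample class label:
``control`` (healthy samples reserved for fitting pairwise reference models),
``healthy`` (healthy samples entering classification as negatives) and
``disease`` (positives). ``healthy_test`` is accepted as an alias of
``healthy`` on input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_LABELS = ("control", "healthy", "disease")
_LABEL_ALIASES = {"healthy_test": "healthy"}


@dataclass
class MethylationMatrix:
    """Dense gene x sample methylation levels with optional class labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, columns are sample ids; every entry in
        [0, 1], no missing values.
    labels
        Optional Series mapping sample id -> class label. Required by the
        classification stage; preprocessing may produce unlabelled matrices.
    """

    values: pd.DataFrame
    labels: pd.Series | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.values
        if not v.index.is_unique:
            dup = v.index[v.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dup[:5]}")
        if not v.columns.is_unique:
            dup = v.columns[v.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dup[:5]}")
        arr = v.to_numpy(dtype=float)
        if np.isnan(arr).any():
            g, s = np.argwhere(np.isnan(arr))[0]
            raise ValueError(
                f"missing value at {v.index[g]},{v.columns[s]}: matrix must be dense"
            )
        if (arr < 0).any() or (arr > 1).any():
            g, s = np.argwhere((arr < 0) | (arr > 1))[0]
            raise ValueError(
                f"value {arr[g, s]!r} out of [0,1] at {v.index[g]},{v.columns[s]}"
            )
        if self.labels is not None:
            lab = self.labels.replace(_LABEL_ALIASES)
            missing = [s for s in v.columns if s not in lab.index]
            if missing:
                raise ValueError(f"samples without label: {missing[:5]}")
            lab = lab.reindex(v.columns)
            bad = sorted(set(lab) - set(VALID_LABELS))
            if bad:
                raise ValueError(f"unknown labels {bad}; expected {VALID_LABELS}")
            self.labels = lab

    # -- accessors ---------------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def _require_labels(self) -> pd.Series:
        if self.labels is None:
            raise ValueError("matrix has no sample labels")
        return self.labels

    @property
    def healthy_ids(self) -> list[str]:
        """All control-eligible healthy samples (labels control or healthy)."""
        lab = self._require_labels()
        return [s for s in self.sample_ids if lab[s] in ("control", "healthy")]

    @property
    def disease_ids(self) -> list[str]:
        lab = self._require_labels()
        return [s for s in self.sample_ids if lab[s] == "disease"]

    def sample_vector(self, sample_id: str) -> np.ndarray:
        return self.values[sample_id].to_numpy(dtype=float)

    def subset_samples(self, sample_ids) -> "MethylationMatrix":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        lab = None if self.labels is None else self.labels.loc[ids]
        return MethylationMatrix(self.values[ids].copy(), lab, dict(self.meta))
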