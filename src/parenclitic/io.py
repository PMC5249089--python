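"""Readers and writers for the package's interchange formats.

Matrices travel as TSV/CSV with a header row of sample ids and the first
column holding gene (or probe) ids; the delimiter is inferred from the file
extension. Labels are a two-column TSV (sample_id, label). All numeric output
is written with 17 significant digits, so round-trips are lossless well past
the 12-digit contract.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .matrix import MethylationMatrix
from .preprocess import ProbeGeneMap, ProbeMatrix

_FLOAT_FMT = "%.17g"


def _sep_for(path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        return ","
    return "\t"


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    if not df.index.is_unique:
        dup = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate row ids {dup[:5]}")
    if not df.columns.is_unique:
        dup = df.columns[df.columns.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dup[:5]}")
    num = df.apply(pd.to_numeric, errors="coerce")
    # literal NaN spellings count as missing values, anything else non-numeric errors
    literal_nan = df.isna() | df.apply(
        lambda col: col.astype(str).str.strip().str.lower().isin(["nan", "na", ""])
    )
    bad = num.isna() & ~literal_nan
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at {df.index[r]},{df.columns[c]}"
        )
    # pd.to_numeric's fast parser is not correctly rounded; reconvert via
    # Python's float() so 17-significant-digit round-trips are exact
    num = df.where(~literal_nan).astype(float)
    num.index.name = None
    num.columns.name = None
    return num


def read_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (sample_id, label)")
    return df.set_index(df.columns[0])[df.columns[1]]


def write_labels(labels: pd.Series, path) -> None:
    labels.rename("label").rename_axis("sample_id").to_frame().to_csv(
        path, sep=_sep_for(path)
    )


def read_matrix(path, labels_path=None) -> MethylationMatrix:
    """Gene-level matrix from TSV/CSV, with optional sample annotation join.

    Out-of-range or non-numeric cells raise with the offending gene,sample
    coordinates.
    """
    num = _read_table(path)
    arr = num.to_numpy(dtype=float)
    out = (arr < 0) | (arr > 1)
    if np.isnan(arr).any():
        r, c = np.argwhere(np.isnan(arr))[0]
        raise ValueError(f"{path}: missing value at {num.index[r]},{num.columns[c]}")
    if out.any():
        r, c = np.argwhere(out)[0]
        raise ValueError(
            f"{path}: value {arr[r, c]!r} out of [0,1] at {num.index[r]},{num.columns[c]}"
        )
    labels = read_labels(labels_path) if labels_path else None
    return MethylationMatrix(num, labels)


def write_matrix(matrix: MethylationMatrix, path, labels_path=None) -> None:
    matrix.values.rename_axis("gene_id").to_csv(
        path, sep=_sep_for(path), float_format=_FLOAT_FMT
    )
    if labels_path and matrix.labels is not None:
        write_labels(matrix.labels, labels_path)


def read_probe_matrix(values_path, detp_path=None) -> ProbeMatrix:
    values = _read_table(values_path)
    detp = _read_table(detp_path) if detp_path else None
    return ProbeMatrix(values, detp)


def write_probe_matrix(pm: ProbeMatrix, values_path, detp_path=None) -> None:
    pm.values.rename_axis("probe_id").to_csv(
        values_path, sep=_sep_for(values_path), float_format=_FLOAT_FMT
    )
    if detp_path and pm.detection_p is not None:
        pm.detection_p.rename_axis("probe_id").to_csv(
            detp_path, sep=_sep_for(detp_path), float_format=_FLOAT_FMT
        )


def read_probe_gene_map(path) -> ProbeGeneMap:
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    return ProbeGeneMap(df)


def read_blacklist(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_features(features: pd.DataFrame, path, kernel: str = "", length_mode: str = "") -> None:
    """Features TSV: one row per sample, 12 named columns + provenance tags."""
    out = features.copy()
    out.insert(0, "kernel", kernel)
    out.insert(1, "length_mode", length_mode)
    out.rename_axis("sample_id").to_csv(path, sep=_sep_for(path), float_format=_FLOAT_FMT)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


# -- run configuration -----------------------------------------------------


@dataclass
class RunConfig:
    """Fully resolved configuration of one end-to-end run."""

    seed: int = 0
    out_dir: str = "parenclitic_out"
    kernel: str = "mahalanobis"
    classifier: str = "rf"
    feature_mode: str = "topology"
    length_mode: str = "direct"
    inner_folds: int = 10
    control_folds: int | None = None
    rf_trees: int = 500
    ridge: float = 1e-8
    top_edges: int | None = None
    matrix: str | None = None  # path; None -> simulate
    labels: str | None = None
    synthetic: dict = field(default_factory=dict)  # SyntheticSpec overrides

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = sorted(set(doc) - known)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {unknown}")
        return cls(**doc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def write_manifest(out_dir, files, extra=None) -> None:
    manifest = {"files": sorted(str(f) for f in files)}
    if extra:
        manifest.update(extra)
    write_json(manifest, Path(out_dir) / "manifest.json")
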