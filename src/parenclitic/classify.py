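"""Two-step cross-validated classification on parenclitic topology indices.

The outer step cross-validates the *choice of control group*: healthy samples
are partitioned into folds (2 folds when fewer than 50 healthy samples are
available, 4 otherwise) and each fold in turn becomes the control group, used
exclusively to fit the pairwise reference models. The remaining healthy
samples join the disease samples as the classification set — so no control
sample is ever classified in its own outer fold. The inner step is ordinary
stratified 10-fold cross-validation of a Random Forest or RBF-kernel SVM on
the 12 topology indices (or, as a baseline, on the raw gene-level methylation
values). Confusion counts are pooled over all inner and outer folds — folds
have unequal sizes, so pooling counts is preferred to averaging rates.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .control_model import fit_mahalanobis, fit_regression
from .matrix import MethylationMatrix
from .network import build_network
from .topology import TopologyFeatures, extract_features

HEALTHY_FOLD_THRESHOLD = 50  # fewer healthy samples than this -> 2 outer folds


@dataclass
class CVConfig:
    """Two-step cross-validation configuration (echoed into every result)."""

    classifier: str = "rf"  # rf | svm
    kernel: str = "mahalanobis"  # mahalanobis | regression
    feature_mode: str = "topology"  # topology | raw
    length_mode: str = "direct"
    control_folds: int | None = None  # None -> auto (2 or 4 by healthy count)
    inner_folds: int = 10
    seed: int = 0
    rf_trees: int = 500
    svm_c: float = 1.0
    ridge: float = 1e-8

    def validate(self) -> None:
        if self.classifier not in ("rf", "svm"):
            raise ValueError(f"classifier must be rf or svm, got {self.classifier!r}")
        if self.kernel not in ("mahalanobis", "regression"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.feature_mode not in ("topology", "raw"):
            raise ValueError(f"unknown feature_mode {self.feature_mode!r}")
        if self.control_folds is not None and self.control_folds not in (2, 4):
            raise ValueError("control_folds must be 2, 4 or None (auto)")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")


@dataclass
class CVResult:
    """Pooled two-step CV outcome."""

    accuracy: float
    specificity: float  # healthy correctly classified negative
    sensitivity: float  # disease correctly classified positive
    confusion: dict  # pooled tn/fp/fn/tp
    fold_counts: list  # per (outer, inner) fold confusion counts
    config: dict
    n_classified: int

    def to_dict(self) -> dict:
        return asdict(self)


def auto_control_folds(n_healthy: int) -> int:
    return 2 if n_healthy < HEALTHY_FOLD_THRESHOLD else 4


def split_control(healthy_ids, n_folds: int, seed: int):
    """Partition healthy samples into control folds.

    Returns a list of (control_ids, heldout_healthy_ids) pairs, one per fold;
    each fold serves as the control group once, the rest of the healthy
    samples are classified as negatives. Folds are disjoint and cover all
    healthy ids.
    """
    ids = list(healthy_ids)
    if len(ids) < n_folds:
        raise ValueError(f"{len(ids)} healthy samples cannot form {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    folds = [sorted(ids[i] for i in chunk) for chunk in np.array_split(order, n_folds)]
    out = []
    for k, fold in enumerate(folds):
        held = sorted(set(ids) - set(fold))
        out.append((fold, held))
    return out


def _make_classifier(config: CVConfig, seed: int):
    if config.classifier == "rf":
        return RandomForestClassifier(
            n_estimators=config.rf_trees, random_state=seed, n_jobs=1
        )
    return make_pipeline(
        StandardScaler(), SVC(kernel="rbf", C=config.svm_c, gamma="scale")
    )


def topology_feature_table(
    matrix: MethylationMatrix, model, sample_ids, length_mode: str = "direct"
) -> pd.DataFrame:
    """Build one network per sample and extract its 12 topology indices."""
    rows = {}
    for sid in sample_ids:
        net = build_network(matrix, sid, model)
        rows[sid] = extract_features(net, length_mode=length_mode).as_dict()
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(TopologyFeatures.ORDER))


def _fold_seed(seed: int, outer: int, salt: int = 0) -> int:
    return int((seed * 1_000_003 + outer * 8191 + salt) % (2**31 - 1))


def run_two_step_cv(matrix: MethylationMatrix, config: CVConfig) -> CVResult:
    """Run the full two-step cross-validation on a labelled matrix."""
    config.validate()
    labels = matrix._require_labels()
    healthy = matrix.healthy_ids
    disease = matrix.disease_ids
    if not healthy or not disease:
        raise ValueError("both healthy and disease samples are required")
    n_folds = config.control_folds or auto_control_folds(len(healthy))
    outer = split_control(healthy, n_folds, config.seed)

    fold_counts = []
    pooled = {"tn": 0, "fp": 0, "fn": 0, "tp": 0}
    for k, (control_ids, held_healthy) in enumerate(outer):
        controls = matrix.subset_samples(control_ids)
        classified = held_healthy + disease
        y = np.array([0] * len(held_healthy) + [1] * len(disease))
        if config.feature_mode == "topology":
            if config.kernel == "regression":
                model = fit_regression(controls)
            else:
                model = fit_mahalanobis(controls, ridge=config.ridge)
            X = topology_feature_table(
                matrix, model, classified, config.length_mode
            ).to_numpy()
        else:
            X = matrix.values[classified].to_numpy().T
        counts = np.bincount(y)
        if counts.min() < config.inner_folds:
            raise ValueError(
                f"outer fold {k}: minority class has {counts.min()} samples, fewer "
                f"than inner_folds={config.inner_folds}; reduce inner_folds or "
                "change the stratification seed"
            )
        skf = StratifiedKFold(
            n_splits=config.inner_folds,
            shuffle=True,
            random_state=_fold_seed(config.seed, k, 1),
        )
        for inner, (tr, te) in enumerate(skf.split(X, y)):
            clf = _make_classifier(config, _fold_seed(config.seed, k, 100 + inner))
            clf.fit(X[tr], y[tr])
            pred = clf.predict(X[te])
            yt = y[te]
            c = {
                "tn": int(((pred == 0) & (yt == 0)).sum()),
                "fp": int(((pred == 1) & (yt == 0)).sum()),
                "fn": int(((pred == 0) & (yt == 1)).sum()),
                "tp": int(((pred == 1) & (yt == 1)).sum()),
            }
            fold_counts.append({"outer": k, "inner": inner, **c})
            for key in pooled:
                pooled[key] += c[key]

    total = sum(pooled.values())
    acc = (pooled["tp"] + pooled["tn"]) / total
    spec = pooled["tn"] / max(pooled["tn"] + pooled["fp"], 1)
    sens = pooled["tp"] / max(pooled["tp"] + pooled["fn"], 1)
    cfg = asdict(config)
    cfg["control_folds_used"] = n_folds
    return CVResult(
        accuracy=acc,
        specificity=spec,
        sensitivity=sens,
        confusion=pooled,
        fold_counts=fold_counts,
        config=cfg,
        n_classified=total,
    )
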