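"""Seeded synthetic methylation cohorts with the pairwise structure the
parenclitic method assumes.

The generator works on the logit scale and squashes through the logistic
function, so values are genuinely bounded in (0, 1) (like beta values) while
the correlation structure stays smooth near the boundaries. Genes are grouped
into disjoint pairs; a configurable fraction of those pairs is *linked*:
their logit values are drawn from a correlated bivariate normal shared by
control and healthy samples. Disease samples perturb every linked pair in one
of two geometries:

* ``off_line``  — the response gene is shifted off the pair's regression line
  by ``delta_perp`` control-residual standard deviations. Regression residuals
  then separate the classes directly.
* ``along_line`` — the point is shifted *along* the regression-line direction
  (1, rho)/sqrt(1 + rho^2) by ``delta_para`` marginal standard deviations.
  Regression residuals are unchanged by construction, but the shifted cluster
  is far from the control cloud, so the Mahalanobis kernel still sees it.
* ``mixed`` — both shifts.

Unlinked genes are independent logit-normal noise, identical across classes.
Ground truth (which pairs are linked/perturbed, directions, magnitudes) is
returned alongside and can be written as a sidecar JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .matrix import MethylationMatrix
from .preprocess import ProbeGeneMap, ProbeMatrix

GEOMETRIES = ("off_line", "along_line", "mixed")


@dataclass
class SyntheticSpec:
    """Study-condition parameters of one synthetic cohort.

    Defaults describe a desk-scale cohort: a 50-gene panel with 60 control,
    60 held-out healthy and 120 disease samples; linked pairs correlate at
    rho = 0.7 on the logit scale with marginal logit spread ``noise_sd`` =
    0.25; half of the gene pairs are linked and perturbed in disease.
    """

    n_genes: int = 50
    n_control: int = 60
    n_healthy: int = 60
    n_disease: int = 120
    pair_correlation: float = 0.7
    fraction_linked_pairs: float = 0.5
    geometry: str = "off_line"
    delta_perp: float = 5.0  # off-line shift, in control residual-sd units
    delta_para: float = 0.0  # along-line shift, in marginal-sd units
    noise_sd: float = 0.25  # marginal logit-scale spread
    mean_range: tuple[float, float] = (-1.5, 1.5)  # per-gene logit means
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_genes, self.n_control, self.n_healthy, self.n_disease) < 0:
            raise ValueError("counts must be nonnegative")
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes")
        if not (-1 < self.pair_correlation < 1):
            raise ValueError(
                f"pair_correlation must lie strictly in (-1,1), got {self.pair_correlation}"
            )
        if not (0 <= self.fraction_linked_pairs <= 1):
            raise ValueError("fraction_linked_pairs must lie in [0,1]")
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"geometry must be one of {GEOMETRIES}")
        if self.delta_perp < 0 or self.delta_para < 0:
            raise ValueError("shift magnitudes must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def _gene_ids(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"g{idx:0{width}d}" for idx in range(n)]


def generate(spec: SyntheticSpec) -> tuple[MethylationMatrix, dict]:
    """Draw one cohort; returns (matrix with labels, ground-truth record)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    g = spec.n_genes
    genes = _gene_ids(g)
    n_total = spec.n_control + spec.n_healthy + spec.n_disease
    labels = (
        ["control"] * spec.n_control
        + ["healthy"] * spec.n_healthy
        + ["disease"] * spec.n_disease
    )
    samples = [f"s{idx:04d}" for idx in range(n_total)]
    disease_cols = np.array([lab == "disease" for lab in labels])

    means = rng.uniform(*spec.mean_range, size=g)
    sd = spec.noise_sd
    rho = spec.pair_correlation

    n_pairs = g // 2
    pair_idx = [(2 * p, 2 * p + 1) for p in range(n_pairs)]
    n_linked = int(round(spec.fraction_linked_pairs * n_pairs))
    linked = rng.choice(n_pairs, size=n_linked, replace=False) if n_linked else np.array([], dtype=int)
    linked_set = set(int(p) for p in linked)
    signs = rng.choice([-1.0, 1.0], size=n_pairs)

    Z = means[:, None] + rng.normal(0.0, sd, size=(g, n_total))
    sigma_perp = sd * np.sqrt(1.0 - rho**2)  # control residual sd (logit scale)
    u = np.array([1.0, rho]) / np.hypot(1.0, rho)  # regression-line direction

    truth_pairs = []
    for p, (a, b) in enumerate(pair_idx):
        if p in linked_set:
            # correlated bivariate draw for the linked pair (overwrites rows)
            cov = sd**2 * np.array([[1.0, rho], [rho, 1.0]])
            zz = rng.multivariate_normal(np.zeros(2), cov, size=n_total).T
            Z[a] = means[a] + zz[0]
            Z[b] = means[b] + zz[1]
            perturbed = disease_cols.any() and (
                spec.delta_perp > 0 or spec.delta_para > 0
            )
            if spec.geometry in ("off_line", "mixed") and spec.delta_perp > 0:
                Z[b, disease_cols] += signs[p] * spec.delta_perp * sigma_perp
            if spec.geometry in ("along_line", "mixed") and spec.delta_para > 0:
                shift = signs[p] * spec.delta_para * sd
                Z[a, disease_cols] += shift * u[0]
                Z[b, disease_cols] += shift * u[1]
            truth_pairs.append(
                {
                    "gene_i": genes[a],
                    "gene_j": genes[b],
                    "linked": True,
                    "perturbed": bool(perturbed),
                    "sign": float(signs[p]),
                    "rho": rho,
                    "delta_perp": spec.delta_perp if spec.geometry != "along_line" else 0.0,
                    "delta_para": spec.delta_para if spec.geometry != "off_line" else 0.0,
                }
            )
    values = pd.DataFrame(expit(Z), index=genes, columns=samples)
    matrix = MethylationMatrix(values, pd.Series(labels, index=samples))
    truth = {
        "spec": {**asdict(spec), "mean_range": list(spec.mean_range)},
        "gene_logit_means": dict(zip(genes, means.tolist())),
        "sigma_perp_logit": sigma_perp,
        "pairs": truth_pairs,
    }
    return matrix, truth


def write_ground_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)


def generate_probe_level(
    spec: SyntheticSpec,
    probes_per_gene: int = 3,
    missing_rate: float = 0.0,
    detp_fail_rate: float = 0.0,
    probe_noise: float = 0.01,
    p_threshold: float = 0.05,
) -> tuple[ProbeMatrix, ProbeGeneMap, dict]:
    """Probe-level expansion of a cohort, exercising the preprocessing stage.

    Each gene expands into ``probes_per_gene`` probes: the gene value plus
    small Gaussian probe noise, clipped to [0, 1]. Entries go missing (NaN)
    at ``missing_rate``; entries fail detection at ``detp_fail_rate`` (their
    detection p-value is drawn above ``p_threshold``, all others below).
    The ground-truth record carries the clean gene-level matrix.
    """
    for name, rate in (("missing_rate", missing_rate), ("detp_fail_rate", detp_fail_rate)):
        if not (0 <= rate <= 1):
            raise ValueError(f"{name} must lie in [0,1], got {rate}")
    if probes_per_gene < 1:
        raise ValueError("probes_per_gene must be >= 1")
    matrix, truth = generate(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7919]))
    gene_vals = matrix.values.to_numpy()
    g, n = gene_vals.shape
    probe_ids, gene_of_probe = [], []
    for gi, gene in enumerate(matrix.gene_ids):
        for k in range(probes_per_gene):
            probe_ids.append(f"cg_{gene}_{k}")
            gene_of_probe.append(gene)
    vals = np.repeat(gene_vals, probes_per_gene, axis=0)
    vals = np.clip(vals + rng.normal(0.0, probe_noise, size=vals.shape), 0.0, 1.0)
    detp = rng.uniform(0.0, p_threshold * 0.8, size=vals.shape)
    fail = rng.random(size=vals.shape) < detp_fail_rate
    detp[fail] = rng.uniform(p_threshold + 0.01, 1.0, size=int(fail.sum()))
    missing = rng.random(size=vals.shape) < missing_rate
    vals[missing] = np.nan
    values = pd.DataFrame(vals, index=probe_ids, columns=matrix.sample_ids)
    detp_df = pd.DataFrame(detp, index=probe_ids, columns=matrix.sample_ids)
    pmap = ProbeGeneMap(pd.DataFrame({"probe_id": probe_ids, "gene_id": gene_of_probe}))
    truth = dict(truth)
    truth["gene_matrix"] = matrix.values.to_dict()
    truth["labels"] = matrix.labels.to_dict()
    return ProbeMatrix(values, detp_df), pmap, truth
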