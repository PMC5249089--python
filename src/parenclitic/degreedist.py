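"""Node-degree distributions and power-law tail fitting.

Healthy-subject parenclitic networks tend to be scale-free: the complementary
cumulative distribution (CCDF) of weighted node degrees — the fraction of
nodes whose degree strictly exceeds a given value — follows a power law
P(deg > x) ~ x^(-gamma) over its tail, appearing as a straight line on
log-log axes. Disease networks typically deviate from that scaling (hubs of
abnormally methylated genes distort the tail), so the quality of the
power-law fit is itself a group-level readout.

The default fit is transparent least squares on (log x, log CCDF); an MLE
alternative (continuous Hill/Clauset-style estimator on the raw degrees) is
available via ``fit_power_law_mle``. Fitted exponents are reported on the
CCDF scale; for an ideal power law with density exponent ``a`` the CCDF
exponent is ``a - 1`` (``PowerLawFit.alpha`` converts back).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .topology import weighted_degrees


@dataclass
class DegreeDistribution:
    """Empirical CCDF of node degrees: P(deg > value), strict inequality."""

    values: np.ndarray  # sorted distinct degree values (or grid points)
    ccdf: np.ndarray  # fraction of nodes with degree > value
    label: str = ""
    degrees: np.ndarray | None = None  # raw degrees when available
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ccdf = np.asarray(self.ccdf, dtype=float)
        if self.values.shape != self.ccdf.shape:
            raise ValueError("values and ccdf must have equal length")
        if (np.diff(self.values) <= 0).any():
            raise ValueError("values must be strictly increasing")
        if (np.diff(self.ccdf) > 1e-12).any():
            raise ValueError("ccdf must be non-increasing")
        if self.ccdf.size and (self.ccdf.min() < -1e-12 or self.ccdf.max() > 1 + 1e-12):
            raise ValueError("ccdf must lie in [0,1]")


@dataclass(frozen=True)
class PowerLawFit:
    """Power-law model of a degree CCDF: P(deg > x) ≈ C * x^(-exponent)."""

    exponent: float  # CCDF-scale exponent (gamma)
    x_min: float
    r_squared: float
    ks: float  # max |empirical - fitted| CCDF over the fitted range
    intercept: float  # log10 C
    n_points: int
    method: str = "ols"

    @property
    def alpha(self) -> float:
        """Density-scale exponent of the implied power law (= exponent + 1)."""
        return self.exponent + 1.0


def ccdf_at(degrees: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """P(deg > g) evaluated at each grid point (strict inequality)."""
    degrees = np.sort(np.asarray(degrees, dtype=float))
    n = degrees.size
    # count of degrees <= g  ->  exceedance = n - count
    counts = np.searchsorted(degrees, np.asarray(grid, dtype=float), side="right")
    return (n - counts) / n


def ccdf(degrees, label: str = "") -> DegreeDistribution:
    """Empirical CCDF at the distinct observed degree values."""
    degrees = np.asarray(degrees, dtype=float)
    if degrees.size == 0:
        raise ValueError("empty degree vector")
    if (degrees < 0).any():
        raise ValueError("degrees must be nonnegative")
    values = np.unique(degrees)
    return DegreeDistribution(values, ccdf_at(degrees, values), label, degrees=degrees)


def degree_grid(max_degree: float, min_degree: float | None = None, n: int = 50) -> np.ndarray:
    """Log-spaced evaluation grid covering the positive degree range."""
    if max_degree <= 0:
        raise ValueError("max degree must be positive")
    lo = min_degree if min_degree and min_degree > 0 else max_degree / 1e4
    return np.geomspace(lo, max_degree, n)


def average_ccdf(nets, grid: np.ndarray | None = None, n_grid: int = 50, label: str = "") -> DegreeDistribution:
    """Pointwise mean of per-network degree CCDFs on a shared grid.

    Networks must share a gene panel. The default grid is log-spaced from the
    smallest positive to the largest degree observed across the group.
    """
    nets = list(nets)
    if not nets:
        raise ValueError("empty network group")
    panel = nets[0].gene_ids
    for net in nets[1:]:
        if net.gene_ids != panel:
            raise ValueError("networks do not share a common gene panel")
    all_deg = [weighted_degrees(net) for net in nets]
    pooled = np.concatenate(all_deg)
    if grid is None:
        pos = pooled[pooled > 0]
        if pos.size == 0:
            raise ValueError("all degrees are zero")
        grid = np.geomspace(pos.min(), pooled.max(), n_grid)
    curves = np.stack([ccdf_at(d, grid) for d in all_deg])
    mean_curve = curves.mean(axis=0)
    return DegreeDistribution(
        np.asarray(grid, dtype=float),
        mean_curve,
        label,
        meta={"n_networks": len(nets), "averaging": "ccdf"},
    )


def pooled_ccdf(nets, label: str = "") -> DegreeDistribution:
    """CCDF of the degrees of all networks pooled into one sample."""
    nets = list(nets)
    if not nets:
        raise ValueError("empty network group")
    pooled = np.concatenate([weighted_degrees(net) for net in nets])
    out = ccdf(pooled, label)
    out.meta["averaging"] = "pooled"
    return out


def fit_power_law(dist: DegreeDistribution, x_min: float | None = None) -> PowerLawFit:
    """Least-squares power-law fit of the CCDF on log-log axes.

    Points with value >= ``x_min`` (default: smallest positive value carrying
    positive CCDF mass) and ccdf > 0 enter an OLS fit of log10(ccdf) on
    log10(value); the reported exponent is minus the slope. Goodness is the
    R^2 of that line and the Kolmogorov-Smirnov distance between the
    empirical and fitted CCDF over the fitted points.
    """
    positive = (dist.values > 0) & (dist.ccdf > 0)
    if x_min is None:
        if not positive.any():
            raise ValueError("no positive-mass points to fit")
        x_min = float(dist.values[positive].min())
    sel = positive & (dist.values >= x_min)
    if sel.sum() < 5:
        raise ValueError(
            f"power-law fit needs >= 5 points with ccdf > 0 above x_min={x_min}; "
            f"got {int(sel.sum())}"
        )
    lx = np.log10(dist.values[sel])
    ly = np.log10(dist.ccdf[sel])
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = float(((ly - pred) ** 2).sum())
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    ks = float(np.abs(dist.ccdf[sel] - np.minimum(10.0**pred, 1.0)).max())
    return PowerLawFit(
        exponent=float(-slope),
        x_min=float(x_min),
        r_squared=r2,
        ks=ks,
        intercept=float(intercept),
        n_points=int(sel.sum()),
        method="ols",
    )


def fit_power_law_mle(dist: DegreeDistribution, x_min: float | None = None) -> PowerLawFit:
    """Continuous maximum-likelihood (Hill) estimate from the raw degrees.

    alpha_hat = 1 + n / sum(ln(x / x_min)) over degrees >= x_min; reported on
    the CCDF scale as ``alpha_hat - 1`` for comparability with the OLS fit.
    """
    if dist.degrees is None:
        raise ValueError("MLE fit needs the raw degree sample (use ccdf())")
    deg = dist.degrees[dist.degrees > 0]
    if x_min is None:
        x_min = float(deg.min())
    tail = deg[deg >= x_min]
    if tail.size < 5:
        raise ValueError("power-law MLE needs >= 5 tail points")
    alpha = 1.0 + tail.size / float(np.log(tail / x_min).sum())
    # goodness via the implied CCDF on the empirical points
    emp = ccdf_at(tail, np.sort(tail))
    fit = (np.sort(tail) / x_min) ** (1.0 - alpha)
    ks = float(np.abs(emp - fit).max())
    return PowerLawFit(
        exponent=alpha - 1.0,
        x_min=float(x_min),
        r_squared=float("nan"),
        ks=ks,
        intercept=float((alpha - 1.0) * np.log10(x_min)),
        n_points=int(tail.size),
        method="mle",
    )
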