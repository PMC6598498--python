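"""Spectral densities of networks and divergences between them.

The spectral density of a graph is the Gaussian-kernel smoothed probability
density of the eigenvalues of its (weighted) adjacency matrix, with each
eigenvalue scaled by 1/n_v.  Densities are estimated on a shared grid so
Kullback-Leibler (KL) and Jensen-Shannon (JS) divergences can be taken by
trapezoidal quadrature.  Bandwidths follow the Sturges or Silverman rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import CorrelationNetwork

logger = logging.getLogger(__name__)

BANDWIDTH_RULES = ("sturges", "silverman")

#: density values below this are treated as zero in the KL support test
SUPPORT_FLOOR = 1e-12

#: points on the shared evaluation grid
GRID_SIZE = 1024

#: kernels are negligible beyond this many bandwidths; sets grid padding
GRID_PAD_BANDWIDTHS = 3.0


@dataclass
class SpectralDensity:
    """A probability density on an ordered grid.

    Invariants: strictly increasing grid, non-negative density, trapezoidal
    integral equal to one within 1e-6.
    """

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.grid.ndim != 1 or self.grid.shape != self.density.shape:
            raise ValueError("grid and density must be 1-d vectors of equal length")
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.density < -1e-15):
            raise ValueError("density must be non-negative")
        self.density = np.clip(self.density, 0.0, None)
        area = float(np.trapezoid(self.density, self.grid))
        if abs(area - 1.0) > 1e-6:
            raise ValueError(f"density must integrate to 1 on its grid (got {area})")
        if not (self.bandwidth > 0):
            raise ValueError("bandwidth must be positive")


def graph_spectrum(network: CorrelationNetwork) -> np.ndarray:
    """Eigenvalues of the adjacency matrix, each divided by n_v, ascending.

    The 1/n_v scaling is a common factor across the groups being compared
    (they share the node set), so it cannot change any test decision.
    """
    eig = np.linalg.eigvalsh(network.adjacency)
    return np.sort(eig) / network.n_nodes


def bandwidth(values, rule: str = "sturges") -> float:
    """Kernel bandwidth by the Sturges or Silverman criterion.

    Sturges: k = ceil(1 + log2(n)) bins, h = range / k.
    Silverman: h = 0.9 * min(sd, IQR/1.34) * n^(-1/5).

    A degenerate sample (zero range/spread) falls back to a small positive
    floor of 1e-3 * max(1, max|x|) so the kernel never has zero width.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        raise ValueError("at least 2 finite values are required")
    if rule == "sturges":
        k = int(np.ceil(1.0 + np.log2(n)))
        h = float(np.ptp(x)) / k
    elif rule == "silverman":
        sd = float(np.std(x, ddof=1))
        iqr = float(stats.iqr(x))
        h = 0.9 * min(sd, iqr / 1.34) * n ** (-0.2)
    else:
        raise ValueError(f"unknown bandwidth rule {rule!r}")
    if not (h > 0) or not np.isfinite(h):
        h = 1e-3 * max(1.0, float(np.max(np.abs(x))))
        logger.warning(
            "degenerate sample for bandwidth selection; falling back to %.3g", h
        )
    return h


def shared_grid(samples, rule: str = "sturges", n_grid: int = GRID_SIZE) -> np.ndarray:
    """Common evaluation grid spanning the union of several samples.

    The grid covers [min - 3*h_max, max + 3*h_max] with ``n_grid`` equally
    spaced points, where h_max is the largest bandwidth among the samples.
    """
    samples = [np.asarray(s, dtype=float).ravel() for s in samples]
    if not samples:
        raise ValueError("at least one sample is required")
    h_max = max(bandwidth(s, rule) for s in samples)
    lo = min(float(np.min(s)) for s in samples) - GRID_PAD_BANDWIDTHS * h_max
    hi = max(float(np.max(s)) for s in samples) + GRID_PAD_BANDWIDTHS * h_max
    return np.linspace(lo, hi, n_grid)


def estimate_density(
    values,
    bandwidth_rule: str = "sturges",
    grid: np.ndarray | None = None,
    n_grid: int = GRID_SIZE,
) -> SpectralDensity:
    """Gaussian-kernel density estimate, renormalized on its grid."""
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("at least 2 finite values are required")
    h = bandwidth(x, bandwidth_rule)
    if grid is None:
        grid = np.linspace(
            x.min() - GRID_PAD_BANDWIDTHS * h,
            x.max() + GRID_PAD_BANDWIDTHS * h,
            n_grid,
        )
    else:
        grid = np.asarray(grid, dtype=float)
    z = (grid[:, None] - x[None, :]) / h
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (x.size * h * np.sqrt(2.0 * np.pi))
    area = float(np.trapezoid(dens, grid))
    if area <= 0:
        raise ValueError("estimated density has zero mass on the supplied grid")
    return SpectralDensity(grid=grid, density=dens / area, bandwidth=h)


def _check_common_grid(*densities: SpectralDensity) -> np.ndarray:
    grid = densities[0].grid
    for d in densities[1:]:
        if d.grid.shape != grid.shape or not np.allclose(d.grid, grid):
            raise ValueError(
                "densities are on different grids; re-evaluate them on a common grid"
            )
    return grid


def floor_density(d: SpectralDensity, floor: float = SUPPORT_FLOOR) -> np.ndarray:
    """Density values with sub-floor entries set to exactly zero."""
    return np.where(d.density < floor, 0.0, d.density)


def mean_density(densities) -> SpectralDensity:
    """Pointwise arithmetic mean of densities on one common grid."""
    densities = list(densities)
    if not densities:
        raise ValueError("at least one density is required")
    grid = _check_common_grid(*densities)
    mean = np.mean([d.density for d in densities], axis=0)
    return SpectralDensity(
        grid=grid, density=mean, bandwidth=max(d.bandwidth for d in densities)
    )


def kl_divergence(
    p: SpectralDensity, q: SpectralDensity, support_floor: float = SUPPORT_FLOOR
) -> float:
    """Kullback-Leibler divergence KL(p || q) by trapezoidal quadrature.

    Uses the 0 log 0 = 0 convention.  Density values below ``support_floor``
    are treated as zero for the support test: if the (floored) reference q
    vanishes anywhere the (floored) p is positive, the result is +inf.
    Non-negative up to quadrature tolerance; clipped at zero.
    """
    grid = _check_common_grid(p, q)
    pd = np.where(p.density < support_floor, 0.0, p.density)
    qd = np.where(q.density < support_floor, 0.0, q.density)
    pos = pd > 0
    if np.any(pos & (qd == 0)):
        return float("inf")
    integrand = np.zeros_like(pd)
    integrand[pos] = pd[pos] * np.log(pd[pos] / qd[pos])
    return max(float(np.trapezoid(integrand, grid)), 0.0)


def js_divergence(p: SpectralDensity, q: SpectralDensity) -> float:
    """Jensen-Shannon divergence: symmetric, finite, zero iff p == q.

    Both densities are floored before averaging so the mixture provably
    contains each one's support and the KL +inf branch cannot fire.
    """
    grid = _check_common_grid(p, q)
    pd = floor_density(p)
    qd = floor_density(q)
    m = (pd + qd) / 2.0  # supp(m) contains supp(pd) and supp(qd) by construction
    total = 0.0
    for dens in (pd, qd):
        pos = dens > 0
        integrand = np.zeros_like(dens)
        integrand[pos] = dens[pos] * np.log(dens[pos] / m[pos])
        total += max(float(np.trapezoid(integrand, grid)), 0.0)
    return total / 2.0


def spectral_entropy(d: SpectralDensity) -> float:
    """Differential entropy -integral(d log d) with 0 log 0 = 0."""
    dens = d.density
    pos = dens > 0
    integrand = np.zeros_like(dens)
    integrand[pos] = dens[pos] * np.log(dens[pos])
    return -float(np.trapezoid(integrand, d.grid))
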