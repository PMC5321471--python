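"""Multi-bandwidth kernel density estimation and mixture-model seeding.

Mutation positions along a protein are smoothed with a Gaussian kernel at 28
bandwidths spanning 2 to 450 amino acids (log-spaced): small bandwidths
resolve single-residue hotspots, large ones entire domains. Each smoothed
density seeds a mixture model — one Gaussian per local maximum plus a uniform
background component — which EM then refines (see :mod:`mutclust.mixture_em`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .mixture_em import GaussianComponent, MixtureModel

logger = logging.getLogger(__name__)

N_BANDWIDTHS = 28
BANDWIDTH_MIN = 2.0
BANDWIDTH_MAX = 450.0

#: Floor applied to seeded component weights before renormalization.
WEIGHT_EPS = 1e-6


def bandwidth_grid() -> np.ndarray:
    """The 28 kernel bandwidths, log-spaced from 2 to 450 amino acids."""
    return np.geomspace(BANDWIDTH_MIN, BANDWIDTH_MAX, N_BANDWIDTHS)


@dataclass
class ScaleDensity:
    """A Gaussian-kernel density of mutation positions at one bandwidth.

    Evaluated on the integer grid 1..L with unit step and no boundary
    reflection; mass smoothed past the gene ends is simply truncated.
    Local maxima/minima come from sign changes of the discrete differences,
    with both gene termini counting as minima.
    """

    bandwidth: float
    grid: np.ndarray
    density: np.ndarray
    maxima: list[int] = field(default_factory=list)
    minima: list[int] = field(default_factory=list)

    def minima_bounds(self, maximum: int) -> tuple[int, int]:
        """The two adjacent local minima flanking a given maximum."""
        lows = np.asarray(self.minima)
        left = lows[lows < maximum]
        right = lows[lows > maximum]
        if left.size == 0 or right.size == 0:
            raise ValueError(f"maximum {maximum} has no flanking minima")
        return int(left.max()), int(right.min())

    def density_at(self, position: int) -> float:
        return float(self.density[position - 1])


def _extrema(density: np.ndarray) -> tuple[list[int], list[int]]:
    """Interior extrema from sign changes of discrete differences (1-based)."""
    d = np.diff(density)
    s = np.sign(d)
    # carry the previous non-zero sign across flat segments
    for i in range(1, len(s)):
        if s[i] == 0:
            s[i] = s[i - 1]
    maxima, minima = [], []
    for i in range(1, len(s)):
        if s[i - 1] > 0 and s[i] < 0:
            maxima.append(i + 1)  # grid index i corresponds to position i+1
        elif s[i - 1] < 0 and s[i] > 0:
            minima.append(i + 1)
    return maxima, minima


def kde(positions: np.ndarray | list[int], bandwidth: float, L: int) -> ScaleDensity:
    """Gaussian-kernel density of mutation positions on the grid 1..L.

    density(x) = (1 / (N h)) * sum_i phi((x - M_i) / h), phi the standard
    normal density. Boundary mass is truncated, not reflected.

    Raises
    ------
    ValueError
        If ``positions`` is empty or ``bandwidth <= 0``.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.size == 0:
        raise ValueError("kde requires at least one mutation position")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    grid = np.arange(1, L + 1, dtype=float)
    z = (grid[:, None] - pos[None, :]) / bandwidth
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (
        pos.size * bandwidth * np.sqrt(2 * np.pi)
    )
    maxima, minima = _extrema(dens)
    # endpoints with a single-sided rise are maxima in spirit, but the seeding
    # needs flanking minima on both sides, so classify termini as minima and
    # keep only interior maxima; a boundary peak still shows as the nearest
    # interior maximum for any realistic bandwidth.
    if not maxima and dens.size:
        # monotone or flat density: treat the argmax as the single maximum
        # unless it sits on a terminus (then the gene has no interior peak).
        am = int(np.argmax(dens)) + 1
        if 1 < am < L:
            maxima = [am]
    minima = sorted(set(minima) | {1, L})
    return ScaleDensity(
        bandwidth=float(bandwidth), grid=grid, density=dens, maxima=maxima, minima=minima
    )


def check_mass_conservation(sd: ScaleDensity, positions: np.ndarray, rtol: float = 0.01) -> bool:
    """Trapezoidal mass vs. mass not truncated at the boundaries."""
    from scipy.stats import norm

    pos = np.asarray(positions, dtype=float)
    expected = float(
        np.mean(
            norm.cdf((len(sd.grid) - pos) / sd.bandwidth)
            - norm.cdf((1 - pos) / sd.bandwidth)
        )
    )
    integral = float(np.trapezoid(sd.density, sd.grid))
    return abs(integral - expected) <= rtol * max(expected, 1e-12)


def seed_mixture(sd: ScaleDensity, syn_fraction: float, L: int) -> MixtureModel:
    """Seed a Gaussians + uniform mixture from one scale's density.

    One Gaussian per local maximum: mean at the maximum, standard deviation
    the distance between the two flanking local minima (gene termini count),
    and raw weight the density at the maximum minus one-n-th of the noise
    weight, floored at a small epsilon. The uniform (noise) component starts
    at the gene's synonymous-mutation fraction; Gaussian weights are scaled
    to fill the remaining 1 - noise mass.
    """
    if not 0 <= syn_fraction < 1:
        raise ValueError("syn_fraction must be in [0, 1)")
    n = len(sd.maxima)
    if n == 0:
        return MixtureModel(L=L, components=[], noise_weight=1.0)
    comps = []
    raw = np.empty(n)
    for k, m in enumerate(sd.maxima):
        lo, hi = sd.minima_bounds(m)
        sigma = float(hi - lo)
        raw[k] = max(sd.density_at(m) - syn_fraction / n, WEIGHT_EPS)
        comps.append(GaussianComponent(mu=float(m), sigma=max(sigma, MixtureModel.SIGMA_MIN), weight=float(raw[k])))
    scale = (1.0 - syn_fraction) / raw.sum()
    comps = [
        GaussianComponent(mu=c.mu, sigma=c.sigma, weight=float(raw[k] * scale))
        for k, c in enumerate(comps)
    ]
    return MixtureModel(L=L, components=comps, noise_weight=float(syn_fraction))


def maxima_counts_by_bandwidth(
    positions: np.ndarray, L: int, bandwidths: np.ndarray | None = None
) -> list[int]:
    """Number of KDE maxima at each bandwidth (coarser scales should not add
    structure; increases are logged as a diagnostic, not an error)."""
    if bandwidths is None:
        bandwidths = bandwidth_grid()
    counts = [len(kde(positions, h, L).maxima) for h in bandwidths]
    for i in range(1, len(counts)):
        if counts[i] > counts[i - 1]:
            logger.debug(
                "maxima count increased with bandwidth: %d -> %d at h=%.3g",
                counts[i - 1], counts[i], bandwidths[i],
            )
    return counts
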