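"""EM fitting of the per-scale Gaussian + uniform mixture.

The generative model for mutation positions on a gene of length L is a
mixture of n Gaussian cluster components and one uniform background
component with emission density 1/L. EM alternates responsibilities
(E-step) with weight/mean/variance updates (M-step); the uniform component
has fixed support, only its weight is re-estimated. Standard deviations are
floored at 0.5 amino acids to keep components non-singular.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

_SQRT_2PI = np.sqrt(2.0 * np.pi)

#: Convergence and numerical-guard defaults.
EM_TOL = 1e-6
EM_MAX_ITER = 500
WEIGHT_COLLAPSE_EPS = 1e-6


@dataclass(frozen=True)
class GaussianComponent:
    mu: float
    sigma: float
    weight: float

    def pdf(self, x: np.ndarray) -> np.ndarray:
        z = (np.asarray(x, dtype=float) - self.mu) / self.sigma
        return np.exp(-0.5 * z**2) / (self.sigma * _SQRT_2PI)


@dataclass
class MixtureModel:
    """n Gaussians + 1 uniform over [1, L]; weights sum to 1."""

    SIGMA_MIN = 0.5

    L: int
    components: list[GaussianComponent] = field(default_factory=list)
    noise_weight: float = 0.0

    def __post_init__(self) -> None:
        total = self.noise_weight + sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"mixture weights sum to {total}, expected 1")
        for c in self.components:
            if not (0 < c.sigma <= self.L):
                raise ValueError(f"sigma {c.sigma} outside (0, L={self.L}]")

    @property
    def n_components(self) -> int:
        return len(self.components)

    def _component_matrix(self, x: np.ndarray) -> np.ndarray:
        """(n_points, n_components + 1) weighted emission matrix; last column
        is the uniform component."""
        x = np.asarray(x, dtype=float)
        cols = [c.weight * c.pdf(x) for c in self.components]
        cols.append(np.full(x.shape, self.noise_weight / self.L))
        return np.column_stack(cols)

    def pdf(self, x: np.ndarray) -> np.ndarray:
        return self._component_matrix(x).sum(axis=1)

    def responsibilities(self, positions: Sequence[int]) -> np.ndarray:
        """Posterior component probabilities, rows = positions; last column
        is the uniform component."""
        m = self._component_matrix(np.asarray(positions))
        return m / m.sum(axis=1, keepdims=True)

    def to_json(self) -> str:
        return json.dumps(
            {
                "L": self.L,
                "noise_weight": self.noise_weight,
                "components": [
                    {"mu": c.mu, "sigma": c.sigma, "weight": c.weight}
                    for c in self.components
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MixtureModel":
        d = json.loads(text)
        return cls(
            L=int(d["L"]),
            components=[GaussianComponent(**c) for c in d["components"]],
            noise_weight=float(d["noise_weight"]),
        )


def log_likelihood(model: MixtureModel, positions: Sequence[int]) -> float:
    """Total log-likelihood sum_i log(noise/L + sum_k w_k G(M_i; mu_k, s_k)).

    Raises
    ------
    ValueError
        If any position lies outside [1, L].
    """
    pos = np.asarray(positions, dtype=float)
    if pos.size == 0:
        return 0.0
    if pos.min() < 1 or pos.max() > model.L:
        raise ValueError("position outside [1, L]")
    dens = model.pdf(pos)
    return float(np.log(dens).sum())


def em_fit(
    model: MixtureModel,
    positions: Sequence[int],
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
    update_means: bool = True,
    update_sigmas: bool = True,
    history: list[float] | None = None,
    _restarted: bool = False,
) -> MixtureModel:
    """Run EM from a seeded model until the log-likelihood gain drops below
    ``tol`` or ``max_iter`` iterations.

    If a Gaussian component's weight collapses below a small epsilon it is
    removed and EM restarts once with the surviving components. Setting
    ``update_means``/``update_sigmas`` to False restricts the M-step to the
    weights (used when re-scoring fixed candidate clusters during merging).
    When ``history`` is a list, the per-iteration log-likelihoods are
    appended to it.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.size == 0:
        raise ValueError("em_fit requires at least one position")
    if model.n_components == 0:
        return MixtureModel(L=model.L, components=[], noise_weight=1.0)

    mus = np.array([c.mu for c in model.components])
    sigmas = np.array([c.sigma for c in model.components])
    weights = np.array([c.weight for c in model.components])
    noise = model.noise_weight
    L = model.L
    n = pos.size

    prev_ll = -np.inf
    for _ in range(max_iter):
        # E-step
        z = (pos[:, None] - mus[None, :]) / sigmas[None, :]
        gauss = np.exp(-0.5 * z**2) / (sigmas[None, :] * _SQRT_2PI)
        weighted = gauss * weights[None, :]
        total = weighted.sum(axis=1) + noise / L
        ll = float(np.log(total).sum())
        if history is not None:
            history.append(ll)
        gamma = weighted / total[:, None]
        gamma_noise = (noise / L) / total

        # M-step
        nk = gamma.sum(axis=0)
        if np.any(nk / n < WEIGHT_COLLAPSE_EPS) and not _restarted:
            keep = nk / n >= WEIGHT_COLLAPSE_EPS
            survivors = [
                GaussianComponent(mu=float(mus[k]), sigma=float(sigmas[k]), weight=float(weights[k]))
                for k in range(len(mus))
                if keep[k]
            ]
            wsum = sum(c.weight for c in survivors) + noise
            survivors = [
                GaussianComponent(c.mu, c.sigma, c.weight / wsum) for c in survivors
            ]
            return em_fit(
                MixtureModel(L=L, components=survivors, noise_weight=noise / wsum),
                positions,
                tol=tol,
                max_iter=max_iter,
                update_means=update_means,
                update_sigmas=update_sigmas,
                history=history,
                _restarted=True,
            )
        weights = nk / n
        noise = float(gamma_noise.sum() / n)
        if update_means:
            safe_nk = np.maximum(nk, 1e-300)
            mus = (gamma * pos[:, None]).sum(axis=0) / safe_nk
        if update_sigmas:
            safe_nk = np.maximum(nk, 1e-300)
            var = (gamma * (pos[:, None] - mus[None, :]) ** 2).sum(axis=0) / safe_nk
            sigmas = np.maximum(np.sqrt(var), MixtureModel.SIGMA_MIN)

        if ll - prev_ll < tol and np.isfinite(prev_ll):
            prev_ll = ll
            break
        prev_ll = ll

    # renormalize against drift
    total_w = weights.sum() + noise
    weights = weights / total_w
    noise = noise / total_w
    comps = [
        GaussianComponent(mu=float(mus[k]), sigma=float(sigmas[k]), weight=float(weights[k]))
        for k in range(len(mus))
    ]
    return MixtureModel(L=L, components=comps, noise_weight=noise)


def sample(model: MixtureModel, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Ancestral sampling of n integer positions from the mixture.

    Component chosen by weight, then a Gaussian draw rounded and clipped to
    [1, L], or a uniform integer for the background component.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n == 0:
        return np.array([], dtype=int)
    probs = np.array([c.weight for c in model.components] + [model.noise_weight])
    probs = probs / probs.sum()
    choice = rng.choice(len(probs), size=n, p=probs)
    out = np.empty(n, dtype=int)
    for k, c in enumerate(model.components):
        mask = choice == k
        if mask.any():
            draws = rng.normal(c.mu, c.sigma, size=int(mask.sum()))
            out[mask] = np.clip(np.rint(draws), 1, model.L).astype(int)
    mask = choice == len(model.components)
    if mask.any():
        out[mask] = rng.integers(1, model.L + 1, size=int(mask.sum()))
    return out
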