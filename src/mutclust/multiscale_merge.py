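"""Merging per-scale mixture models into one multiscale cluster set.

Candidate clusters are harvested from the EM-refined mixtures at every
bandwidth, keeping components whose interval holds at least 15 mutations.
Candidates are placed in a binary tree by agglomerative clustering on the
unsigned area between their (unit-mass) Gaussian curves, and the tree is
flattened bottom-up: at each internal node the non-overlapping subset of the
two children's cluster sets minimizing AICc is kept. The result is a single
set of non-overlapping clusters per gene, each scored by the log emission
ratio of its Gaussian against the uniform background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.integrate import quad

from .kde_scales import bandwidth_grid, kde, seed_mixture
from .mixture_em import GaussianComponent, MixtureModel, em_fit, log_likelihood
from .mutation_data import Cluster, GeneTable

logger = logging.getLogger(__name__)

MIN_CLUSTER_MUTATIONS = 15
#: Above this pool-union size the per-node subset search switches from
#: exhaustive enumeration to greedy forward selection.
EXHAUSTIVE_LIMIT = 12
#: Number of alternative selections each tree node carries upward; a small
#: beam keeps near-tied overlap resolutions alive until more context exists.
BEAM_WIDTH = 4

_SQRT_2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class Candidate:
    """A candidate cluster from one scale: interval + generating Gaussian."""

    start: int
    end: int
    mu: float
    sigma: float
    weight: float
    n_mutations: int
    bandwidth: float

    def overlaps(self, other: "Candidate") -> bool:
        return not (self.end < other.start or other.end < self.start)


# ---------------------------------------------------------------------------
# Interval extraction and scoring
# ---------------------------------------------------------------------------


def component_to_interval(
    model: MixtureModel, component_index: int, positions: Sequence[int]
) -> tuple[int, int] | None:
    """Interval spanned by mutations assigned (argmax responsibility) to one
    Gaussian component; ``None`` when nothing is assigned. Responsibility
    ties break toward the lower component index (argmax convention)."""
    pos = np.asarray(positions, dtype=int)
    gamma = model.responsibilities(pos)
    assigned = pos[np.argmax(gamma, axis=1) == component_index]
    if assigned.size == 0:
        return None
    return int(assigned.min()), int(assigned.max())


def score_cluster(mu: float, sigma: float, positions_in_cluster: Sequence[int], L: int) -> float:
    """Cluster score S_c = sum_i log(G(M_i; mu, sigma) / (1/L)).

    G is the unit-mass normal density of the cluster's generating Gaussian;
    1/L the uniform emission over the gene. Empty mutation set scores 0.
    """
    pos = np.asarray(positions_in_cluster, dtype=float)
    if pos.size == 0:
        return 0.0
    if sigma <= 0 or L < 1:
        raise ValueError("sigma must be > 0 and L >= 1")
    logg = -0.5 * ((pos - mu) / sigma) ** 2 - np.log(sigma * _SQRT_2PI)
    return float((logg + np.log(L)).sum())


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike information criterion with the finite-sample correction.

    AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1); +inf when n <= k+1 so model
    selection avoids over-parameterized candidates.
    """
    if n <= k + 1:
        return np.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def unsigned_area_distance(
    g1: tuple[float, float], g2: tuple[float, float]
) -> float:
    """Unsigned area between two unit-mass Gaussian curves; in [0, 2].

    Computed by adaptive quadrature over a range covering both curves'
    supports. Symmetric in its arguments.
    """
    mu1, s1 = g1
    mu2, s2 = g2
    if s1 <= 0 or s2 <= 0:
        raise ValueError("sigma must be positive")
    if mu1 == mu2 and s1 == s2:
        return 0.0

    def f(x: float) -> float:
        a = np.exp(-0.5 * ((x - mu1) / s1) ** 2) / (s1 * _SQRT_2PI)
        b = np.exp(-0.5 * ((x - mu2) / s2) ** 2) / (s2 * _SQRT_2PI)
        return abs(a - b)

    lo = min(mu1 - 8 * s1, mu2 - 8 * s2)
    hi = max(mu1 + 8 * s1, mu2 + 8 * s2)
    val, _ = quad(f, lo, hi, limit=200)
    return float(min(val, 2.0))


# ---------------------------------------------------------------------------
# Candidate pool
# ---------------------------------------------------------------------------


def scale_candidates(
    gene_table: GeneTable,
    bandwidths: np.ndarray | None = None,
    min_mutations: int = MIN_CLUSTER_MUTATIONS,
) -> tuple[list[Candidate], dict[float, MixtureModel]]:
    """Fit a mixture per bandwidth and harvest eligible candidate clusters.

    A component becomes a candidate when the interval spanned by its assigned
    mutations holds at least ``min_mutations`` mutations (all classes).
    Returns the candidate pool and the fitted per-scale models.
    """
    if bandwidths is None:
        bandwidths = bandwidth_grid()
    positions = gene_table.positions
    if positions.size == 0:
        return [], {}
    L = gene_table.length_aa
    syn = gene_table.synonymous_fraction
    pool: list[Candidate] = []
    models: dict[float, MixtureModel] = {}
    for h in bandwidths:
        sd = kde(positions, float(h), L)
        seed = seed_mixture(sd, syn, L)
        if seed.n_components == 0:
            models[float(h)] = seed
            continue
        model = em_fit(seed, positions)
        models[float(h)] = model
        for k, comp in enumerate(model.components):
            interval = component_to_interval(model, k, positions)
            if interval is None:
                continue
            start, end = interval
            n_in = int(((positions >= start) & (positions <= end)).sum())
            if n_in >= min_mutations:
                pool.append(
                    Candidate(
                        start=start,
                        end=end,
                        mu=comp.mu,
                        sigma=comp.sigma,
                        weight=comp.weight,
                        n_mutations=n_in,
                        bandwidth=float(h),
                    )
                )
    return pool, models


# ---------------------------------------------------------------------------
# Tree construction and greedy AICc flattening
# ---------------------------------------------------------------------------


def build_tree(pool: Sequence[Candidate]):
    """Binary tree over candidates by agglomerative (single-linkage)
    clustering of pairwise unsigned-area distances. Leaf ids index ``pool``.
    """
    if not pool:
        raise ValueError("candidate pool is empty")
    if len(pool) == 1:
        return _SingleLeaf(0)
    m = len(pool)
    cond = np.empty(m * (m - 1) // 2)
    idx = 0
    for i in range(m):
        for j in range(i + 1, m):
            cond[idx] = unsigned_area_distance(
                (pool[i].mu, pool[i].sigma), (pool[j].mu, pool[j].sigma)
            )
            idx += 1
    z = linkage(cond, method="single")
    return to_tree(z)


class _SingleLeaf:
    """Minimal stand-in for a scipy ClusterNode when the pool has one item."""

    def __init__(self, idx: int) -> None:
        self.id = idx

    def is_leaf(self) -> bool:  # noqa: D102 - scipy API mirror
        return True


def _selection_aicc(
    selection: tuple[int, ...],
    pool: Sequence[Candidate],
    positions: np.ndarray,
    syn_fraction: float,
    L: int,
    cache: dict[tuple[int, ...], float],
) -> float:
    """AICc of the mixture implied by a candidate selection.

    The mixture holds the selected Gaussians plus the uniform background;
    weights are re-fit by a single EM pass (means and sigmas fixed), then
    AICc is computed with k = 3 * n_gaussians + 1 parameters.
    """
    if selection in cache:
        return cache[selection]
    n = positions.size
    k = 3 * len(selection) + 1
    if not selection:
        ll = n * np.log(1.0 / L)
        val = aicc(ll, k, n)
        cache[selection] = val
        return val
    noise = min(max(syn_fraction, 0.05), 0.95)
    w = (1.0 - noise) / len(selection)
    model = MixtureModel(
        L=L,
        components=[
            # sigma capped at L: a candidate broader than the gene is
            # indistinguishable from background over [1, L]
            GaussianComponent(mu=pool[i].mu, sigma=min(pool[i].sigma, L), weight=w)
            for i in selection
        ],
        noise_weight=noise,
    )
    refit = em_fit(
        model, positions, max_iter=1, update_means=False, update_sigmas=False
    )
    ll = log_likelihood(refit, positions)
    val = aicc(ll, k, n)
    cache[selection] = val
    return val


def _is_nonoverlapping(selection: Sequence[int], pool: Sequence[Candidate]) -> bool:
    items = sorted((pool[i].start, pool[i].end) for i in selection)
    return all(a[1] < b[0] for a, b in zip(items, items[1:]))


def _total_length(selection: Sequence[int], pool: Sequence[Candidate]) -> int:
    return sum(pool[i].end - pool[i].start + 1 for i in selection)


def _is_maximal(sel: Sequence[int], union: Sequence[int], pool: Sequence[Candidate]) -> bool:
    """True if no further union member can join ``sel`` without overlap."""
    chosen = set(sel)
    for i in union:
        if i in chosen:
            continue
        if all(not pool[i].overlaps(pool[j]) for j in sel):
            return False
    return True


def _selection_key(
    sel: tuple[int, ...],
    pool: Sequence[Candidate],
    positions: np.ndarray,
    syn_fraction: float,
    L: int,
    cache: dict[tuple[int, ...], float],
) -> tuple:
    """Deterministic ranking: AICc, then fewer clusters, then shorter total
    interval, then lexicographic."""
    return (
        _selection_aicc(sel, pool, positions, syn_fraction, L, cache),
        len(sel),
        _total_length(sel, pool),
        sel,
    )


def _ranked_subsets(
    union: Sequence[int],
    pool: Sequence[Candidate],
    positions: np.ndarray,
    syn_fraction: float,
    L: int,
    cache: dict[tuple[int, ...], float],
    allow_drop: bool,
    top: int,
) -> list[tuple[int, ...]]:
    """The ``top`` best (by :func:`_selection_key`) non-overlapping subsets
    of ``union``; restricted to maximal subsets when ``allow_drop`` is
    False. Assumes ``len(union) <= EXHAUSTIVE_LIMIT``."""
    m = len(union)
    scored = []
    for mask in range(0 if allow_drop else 1, 1 << m):
        sel = tuple(union[i] for i in range(m) if mask >> i & 1)
        if not _is_nonoverlapping(sel, pool):
            continue
        if not allow_drop and sel and not _is_maximal(sel, union, pool):
            continue
        scored.append((_selection_key(sel, pool, positions, syn_fraction, L, cache), sel))
    scored.sort()
    return [s for _, s in scored[:top]]


def _best_subset(
    union: list[int],
    pool: Sequence[Candidate],
    positions: np.ndarray,
    syn_fraction: float,
    L: int,
    cache: dict[tuple[int, ...], float],
    allow_drop: bool = True,
) -> tuple[int, ...]:
    """Non-overlapping subset of ``union`` minimizing AICc.

    With ``allow_drop=False`` only *maximal* non-overlapping subsets compete:
    a candidate conflicting with nothing is never discarded (used at internal
    tree nodes, where the rest of the gene's structure is not yet in view and
    a lone cluster can look spuriously unhelpful). Exhaustive over all
    subsets up to EXHAUSTIVE_LIMIT candidates; greedy forward selection
    beyond that. Ties prefer fewer clusters, then smaller total interval
    length, then lexicographic order (deterministic output).
    """

    def key(sel: tuple[int, ...]) -> tuple:
        return (
            _selection_aicc(sel, pool, positions, syn_fraction, L, cache),
            len(sel),
            _total_length(sel, pool),
            sel,
        )

    if len(union) <= EXHAUSTIVE_LIMIT:
        ranked = _ranked_subsets(union, pool, positions, syn_fraction, L, cache, allow_drop, top=1)
        return ranked[0] if ranked else ()
    # greedy forward selection: repeatedly add the feasible candidate with the
    # best resulting key; stop early only when drops are allowed
    current: tuple[int, ...] = ()
    current_key = key(current)
    remaining = list(union)
    while remaining:
        trials = []
        for i in remaining:
            sel = tuple(sorted(current + (i,)))
            if _is_nonoverlapping(sel, pool):
                trials.append((key(sel), i, sel))
        if not trials:
            break
        trials.sort()
        if not allow_drop or trials[0][0] < current_key:
            current_key, picked, current = trials[0][0], trials[0][1], trials[0][2]
            remaining.remove(picked)
        else:
            break
    return current


def greedy_flatten(
    tree,
    pool: Sequence[Candidate],
    positions: Sequence[int],
    syn_fraction: float,
    L: int,
) -> list[Candidate]:
    """Flatten the candidate tree into a non-overlapping cluster set.

    Post-order recursion: each leaf proposes its own candidate; each internal
    node merges its children's selections by choosing, among the maximal
    non-overlapping subsets of their union, the one minimizing AICc — overlap
    conflicts are resolved greedily, but a candidate conflicting with nothing
    survives to the root, where the gene's full structure is in view. The
    root then re-optimizes over *all* non-overlapping subsets of its union
    (so the final set may be empty: pure background). As a final guard the
    result is compared against every single-bandwidth candidate set and
    replaced if one scores a lower AICc — the multiscale answer is then never
    worse than any individual scale.
    """
    pos = np.asarray(positions, dtype=int)
    cache: dict[tuple[int, ...], float] = {}

    def key(sel: tuple[int, ...]) -> tuple:
        return _selection_key(sel, pool, pos, syn_fraction, L, cache)

    def visit(node) -> list[tuple[int, ...]]:
        if node.is_leaf():
            return [(int(node.id),)]
        beams_l = visit(node.get_left())
        beams_r = visit(node.get_right())
        merged: set[tuple[int, ...]] = set()
        for sl in beams_l:
            for sr in beams_r:
                union = sorted(set(sl) | set(sr))
                if len(union) <= EXHAUSTIVE_LIMIT:
                    merged.update(
                        _ranked_subsets(
                            union, pool, pos, syn_fraction, L, cache,
                            allow_drop=False, top=BEAM_WIDTH,
                        )
                    )
                else:
                    merged.add(
                        _best_subset(
                            union, pool, pos, syn_fraction, L, cache, allow_drop=False
                        )
                    )
        return sorted(merged, key=key)[:BEAM_WIDTH]

    selection: tuple[int, ...] = ()
    best_key = None
    for survivors in visit(tree):
        sel = _best_subset(list(survivors), pool, pos, syn_fraction, L, cache)
        k = key(sel)
        if best_key is None or k < best_key:
            selection, best_key = sel, k
    for h in sorted({c.bandwidth for c in pool}):
        sel = tuple(i for i, c in enumerate(pool) if c.bandwidth == h)
        if not _is_nonoverlapping(sel, pool):
            continue
        k = key(sel)
        if k < best_key:
            selection, best_key = sel, k
    return [pool[i] for i in sorted(selection, key=lambda i: pool[i].start)]


# ---------------------------------------------------------------------------
# Top-level per-gene pipeline
# ---------------------------------------------------------------------------


def find_clusters(
    gene_table: GeneTable,
    bandwidths: np.ndarray | None = None,
    min_mutations: int = MIN_CLUSTER_MUTATIONS,
) -> list[Cluster]:
    """Run the full multiscale pipeline on one gene.

    KDE at every bandwidth -> seeded EM mixture per scale -> candidate pool
    (>= ``min_mutations`` mutations each) -> hierarchical tree -> greedy AICc
    flattening -> scored, non-overlapping clusters. An empty list means all
    the gene's mutations were classified as uniform background.
    """
    pool, _ = scale_candidates(gene_table, bandwidths, min_mutations)
    if not pool:
        return []
    positions = gene_table.positions
    L = gene_table.length_aa
    tree = build_tree(pool)
    chosen = greedy_flatten(tree, pool, positions, gene_table.synonymous_fraction, L)
    clusters = []
    for cand in chosen:
        in_cluster = positions[(positions >= cand.start) & (positions <= cand.end)]
        clusters.append(
            Cluster(
                gene=gene_table.gene,
                start=cand.start,
                end=cand.end,
                mu=cand.mu,
                sigma=cand.sigma,
                weight=cand.weight,
                n_mutations=int(in_cluster.size),
                score=score_cluster(cand.mu, cand.sigma, in_cluster, L),
                bandwidth=cand.bandwidth,
            )
        )
    _assert_nonoverlapping(clusters)
    logger.info("%s: %d clusters from %d candidates", gene_table.gene, len(clusters), len(pool))
    return clusters


def _assert_nonoverlapping(clusters: Sequence[Cluster]) -> None:
    ordered = sorted(clusters, key=lambda c: c.start)
    for a, b in zip(ordered, ordered[1:]):
        if a.end >= b.start:
            raise AssertionError(
                f"overlapping final clusters: {a.start}-{a.end} and {b.start}-{b.end}"
            )


def exhaustive_best_selection(
    pool: Sequence[Candidate],
    positions: Sequence[int],
    syn_fraction: float,
    L: int,
) -> tuple[tuple[int, ...], float]:
    """Reference search: the global AICc optimum over all non-overlapping
    subsets of the pool (exponential; intended for pools of ~10 or fewer)."""
    pos = np.asarray(positions, dtype=int)
    cache: dict[tuple[int, ...], float] = {}
    best = _best_subset(list(range(len(pool))), pool, pos, syn_fraction, L, cache)
    if len(pool) > EXHAUSTIVE_LIMIT:
        raise ValueError("exhaustive search restricted to small pools")
    return best, _selection_aicc(best, pool, pos, syn_fraction, L, cache)
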