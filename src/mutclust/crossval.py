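"""Cross-validation machinery: balanced splits, cluster conservation,
generative held-out likelihood, and association robustness.

Robustness of the clustering is probed by splitting the sample set in two,
re-running the pipeline on each half, and asking (a) whether clusters found
in one half are re-found (>50% interval overlap) in the other, and (b) how
well the mixture model fitted on one half predicts the held-out half's
mutation positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import spearmanr

from .enrichment_assoc import AssociationResult
from .mixture_em import MixtureModel, log_likelihood
from .mutation_data import Cluster, GeneTable, subset_gene_table

logger = logging.getLogger(__name__)

BALANCE_TOLERANCE = 0.05
MAX_SPLIT_RETRIES = 200


@dataclass
class PartitionPair:
    """Two disjoint sample halves with their per-gene mutation tables."""

    samples_a: set[str]
    samples_b: set[str]
    tables_a: list[GeneTable]
    tables_b: list[GeneTable]


def _mutation_balance(tables_a: Sequence[GeneTable], tables_b: Sequence[GeneTable]) -> float:
    """Worst relative difference between partitions in non-synonymous and
    synonymous mutation counts."""
    def counts(tables: Sequence[GeneTable]) -> tuple[int, int]:
        nonsyn = sum(r.non_synonymous for t in tables for r in t.records)
        total = sum(len(t.records) for t in tables)
        return nonsyn, total - nonsyn

    na, sa = counts(tables_a)
    nb, sb = counts(tables_b)
    diffs = []
    for x, y in ((na, nb), (sa, sb)):
        if x + y > 0:
            diffs.append(abs(x - y) / ((x + y) / 2))
    return max(diffs, default=0.0)


def balanced_split(
    gene_tables: Sequence[GeneTable],
    seed: int,
    tolerance: float = BALANCE_TOLERANCE,
    max_retries: int = MAX_SPLIT_RETRIES,
    stratify_by_tumor_type: bool = False,
) -> PartitionPair:
    """Random sample-level split into two equal halves (sizes within 1),
    re-drawn until non-synonymous and synonymous mutation counts differ by at
    most ``tolerance`` (relative). If no draw within ``max_retries`` meets
    the tolerance the best split seen is returned with a warning.
    """
    all_samples = sorted({r.sample_id for t in gene_tables for r in t.records})
    if len(all_samples) < 2:
        raise ValueError("balanced_split requires at least 2 samples")
    rng = np.random.default_rng(seed)
    by_type: dict[str, list[str]] = {}
    if stratify_by_tumor_type:
        type_of = {
            r.sample_id: r.tumor_type for t in gene_tables for r in t.records
        }
        for s in all_samples:
            by_type.setdefault(type_of[s], []).append(s)

    best: PartitionPair | None = None
    best_balance = np.inf
    for _ in range(max_retries):
        if stratify_by_tumor_type:
            a: list[str] = []
            for group in by_type.values():
                perm = rng.permutation(group)
                a.extend(perm[: len(perm) // 2 + int(rng.random() < 0.5 and len(perm) % 2)])
            set_a = set(a)
        else:
            perm = rng.permutation(all_samples)
            set_a = set(perm[: len(all_samples) // 2])
        set_b = set(all_samples) - set_a
        tables_a = [subset_gene_table(t, set_a) for t in gene_tables]
        tables_b = [subset_gene_table(t, set_b) for t in gene_tables]
        balance = _mutation_balance(tables_a, tables_b)
        pair = PartitionPair(set_a, set_b, tables_a, tables_b)
        if balance < best_balance:
            best, best_balance = pair, balance
        if balance <= tolerance and abs(len(set_a) - len(set_b)) <= 1:
            return pair
    logger.warning(
        "balanced_split: tolerance %.3f not met after %d retries "
        "(best relative difference %.3f); returning best split",
        tolerance, max_retries, best_balance,
    )
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Cluster conservation
# ---------------------------------------------------------------------------


def _covered(x: Cluster, y: Cluster) -> bool:
    """True if strictly more than 50% of x's interval is inside y's."""
    inter = min(x.end, y.end) - max(x.start, y.start) + 1
    return inter / x.length > 0.5


def conservation(
    clusters_a: Sequence[Cluster], clusters_b: Sequence[Cluster]
) -> tuple[float, list[bool]]:
    """Fraction of A-clusters conserved in B, plus per-cluster flags.

    A cluster is conserved when, against some same-gene cluster of the other
    set, either interval covers the other by strictly more than 50%.
    Returns ``(nan, [])`` when A is empty.
    """
    by_gene: dict[str, list[Cluster]] = {}
    for c in clusters_b:
        by_gene.setdefault(c.gene, []).append(c)
    flags = []
    for x in clusters_a:
        flags.append(
            any(_covered(x, y) or _covered(y, x) for y in by_gene.get(x.gene, []))
        )
    frac = float(np.mean(flags)) if flags else float("nan")
    return frac, flags


# ---------------------------------------------------------------------------
# Generative held-out likelihood
# ---------------------------------------------------------------------------


def generative_validation(
    models_a: Mapping[str, MixtureModel],
    models_b: Mapping[str, MixtureModel],
    tables_a: Sequence[GeneTable],
    tables_b: Sequence[GeneTable],
) -> tuple[list[tuple[str, float, float]], float]:
    """Held-out log-likelihood per gene in both directions.

    For each gene present in both partitions, evaluates the partition-A model
    on partition-B data and vice versa. Returns the per-gene pairs
    ``(gene, ll_A_on_B, ll_B_on_A)`` and the Spearman rank correlation
    between the two directions across genes.
    """
    pos_a = {t.gene: t.positions for t in tables_a if len(t.records)}
    pos_b = {t.gene: t.positions for t in tables_b if len(t.records)}
    rows = []
    for gene in sorted(set(models_a) & set(models_b) & set(pos_a) & set(pos_b)):
        ll_ab = log_likelihood(models_a[gene], pos_b[gene])
        ll_ba = log_likelihood(models_b[gene], pos_a[gene])
        rows.append((gene, ll_ab, ll_ba))
    if len(rows) < 2:
        return rows, float("nan")
    rho = spearmanr([r[1] for r in rows], [r[2] for r in rows]).statistic
    return rows, float(rho)


# ---------------------------------------------------------------------------
# Association robustness
# ---------------------------------------------------------------------------


def _clusters_match(fa: str, fb: str, clusters_a: Mapping[str, Cluster], clusters_b: Mapping[str, Cluster]) -> bool:
    if fa == fb:
        return True
    ca, cb = clusters_a.get(fa), clusters_b.get(fb)
    if ca is None or cb is None:
        return False
    return ca.gene == cb.gene and (_covered(ca, cb) or _covered(cb, ca))


def association_robustness(
    results_a: Sequence[AssociationResult],
    results_b: Sequence[AssociationResult],
    fdr: float = 0.10,
    clusters_a: Sequence[Cluster] | None = None,
    clusters_b: Sequence[Cluster] | None = None,
) -> tuple[float, float]:
    """Conserved fraction and log-p rank correlation between partitions.

    An A-significant association (at FDR ``fdr``) is conserved if B has a
    significant association with the same target whose feature matches —
    identically, or (when cluster sets are supplied) via the >50% interval
    overlap rule. Returns ``(nan, nan)`` with a warning when A has no
    significant associations.
    """
    map_a = {c.feature_id: c for c in clusters_a} if clusters_a else {}
    map_b = {c.feature_id: c for c in clusters_b} if clusters_b else {}
    sig_a = [r for r in results_a if r.significant_at.get(fdr)]
    sig_b = [r for r in results_b if r.significant_at.get(fdr)]
    if not sig_a:
        logger.warning("association_robustness: no significant associations in A")
        return float("nan"), float("nan")
    conserved = 0
    logp_a, logp_b = [], []
    for ra in sig_a:
        matches = [
            rb
            for rb in sig_b
            if rb.target == ra.target
            and _clusters_match(ra.feature_id, rb.feature_id, map_a, map_b)
        ]
        if matches:
            conserved += 1
            best = min(matches, key=lambda r: r.p_value)
            logp_a.append(np.log(max(ra.p_value, 1e-300)))
            logp_b.append(np.log(max(best.p_value, 1e-300)))
    frac = conserved / len(sig_a)
    rho = float("nan")
    if len(logp_a) >= 2 and np.std(logp_a) > 0 and np.std(logp_b) > 0:
        rho = float(spearmanr(logp_a, logp_b).statistic)
    return frac, rho
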