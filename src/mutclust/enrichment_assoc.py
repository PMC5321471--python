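"""Downstream association statistics for mutation-cluster features.

Covers: Fisher's-exact tumor-type enrichment of clusters, Kruskal–Wallis
tests between binary mutation features and continuous targets (gene
expression, drug ln-IC50), the Empirical Brown's Method (EBM) for combining
dependent expression p-values globally and per pathway, Benjamini–Hochberg
FDR control, per-gene up/down direction calls, and the binomial in-cluster
enrichment test for cell-line mutation data.

EBM background: Fisher's method sums -2 ln p across tests and refers the sum
to chi-square with 2k df, which is anti-conservative when the underlying
variables are correlated (co-expressed pathway genes). EBM keeps the
chi-square form but rescales it: each target's raw data row is transformed to
w(s) = -2 ln F_hat(x(s)) via its empirical right-tail survival function, the
covariance of those transforms estimates the extra variance of the sum, and a
scaled chi-square (moment-matched scale c and df f) replaces the nominal one.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .feature_matrix import FeatureMatrix
from .mutation_data import Cluster

logger = logging.getLogger(__name__)

DEFAULT_FDR_LEVELS = (0.01, 0.05, 0.10, 0.25)


class Direction(enum.Enum):
    UP = "up"
    DOWN = "down"
    NA = "NA"


@dataclass
class AssociationResult:
    """One (feature, target) association with its combined/raw p-value."""

    feature_id: str
    target: str  # expression gene, pathway name, "GLOBAL", or drug name
    p_value: float
    kind: str = "raw"  # raw | global | pathway | drug | enrichment
    significant_at: dict[float, bool] = field(default_factory=dict)
    direction: Direction = Direction.NA
    direction_calls: dict[str, Direction] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Fisher's-exact tumor-type enrichment
# ---------------------------------------------------------------------------


def fisher_enrichment(table: np.ndarray | Sequence[Sequence[int]], alternative: str = "two-sided") -> float:
    """Fisher's exact p-value for a 2x2 cluster x tumor-type table.

    Rows: sample has / lacks a mutation in the cluster; columns: sample is /
    is not of the tumor type. An empty margin carries no information -> p=1.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a non-negative 2x2 table")
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        return 1.0
    return float(stats.fisher_exact(t, alternative=alternative)[1])


def cluster_tumor_enrichment(
    matrices: Mapping[str, FeatureMatrix],
    clusters: Sequence[Cluster],
    fdr_levels: Sequence[float] = DEFAULT_FDR_LEVELS,
    alternative: str = "two-sided",
) -> list[AssociationResult]:
    """Fisher+BH enrichment of every cluster in every tumor type.

    ``matrices`` maps tumor type -> per-type feature matrix over disjoint
    sample sets; contingency tables are built across the union (pan-cancer)
    sample universe. All (cluster, tumor type) p-values are BH-corrected
    together, flagged at each requested FDR level.
    """
    cluster_ids = [c.feature_id for c in clusters]
    membership: dict[str, dict[str, np.ndarray]] = {}
    counts: dict[str, int] = {}
    for tt, fm in matrices.items():
        counts[tt] = len(fm.samples)
        membership[tt] = {
            cid: fm.values[cid].to_numpy() if cid in fm.values.columns else np.zeros(len(fm.samples), dtype=int)
            for cid in cluster_ids
        }
    total_samples = sum(counts.values())

    results = []
    for cid in cluster_ids:
        pos_by_tt = {tt: int(membership[tt][cid].sum()) for tt in matrices}
        total_pos = sum(pos_by_tt.values())
        for tt in matrices:
            a = pos_by_tt[tt]
            b = total_pos - a
            c = counts[tt] - a
            d = (total_samples - counts[tt]) - b
            p = fisher_enrichment([[a, b], [c, d]], alternative=alternative)
            results.append(
                AssociationResult(feature_id=cid, target=tt, p_value=p, kind="enrichment")
            )
    _apply_bh(results, fdr_levels)
    return results


def _apply_bh(results: list[AssociationResult], fdr_levels: Sequence[float]) -> None:
    ps = np.array([r.p_value for r in results])
    if ps.size == 0:
        return
    for q in fdr_levels:
        flags = bh_fdr(ps, q)
        for r, f in zip(results, flags):
            r.significant_at[q] = bool(f)


# ---------------------------------------------------------------------------
# Kruskal–Wallis
# ---------------------------------------------------------------------------


def kruskal_wallis(feature: np.ndarray, values: np.ndarray) -> float:
    """Two-group Kruskal–Wallis p-value (tie-corrected H, chi-square 1 df).

    Missing values are dropped first. Returns ``nan`` when either group is
    empty after complete-case filtering, or when all values are tied.
    """
    feature = np.asarray(feature)
    values = np.asarray(values, dtype=float)
    ok = ~np.isnan(values)
    feature, values = feature[ok], values[ok]
    g1 = values[feature == 1]
    g0 = values[feature == 0]
    if g1.size == 0 or g0.size == 0:
        return float("nan")
    if np.all(values == values[0]):
        return 1.0
    return float(stats.kruskal(g1, g0)[1])


# ---------------------------------------------------------------------------
# Empirical Brown's Method
# ---------------------------------------------------------------------------


def _ebm_transform(row: np.ndarray) -> np.ndarray:
    """w(s) = -2 ln F_hat(x(s)): right-tail empirical survival with averaged
    ranks, clipped at 1/(10 s) so logs stay finite."""
    row = np.asarray(row, dtype=float)
    s = row.size
    # averaged descending ranks: largest value -> rank 1
    order_rank = stats.rankdata(-row, method="average")
    surv = order_rank / s
    surv = np.clip(surv, 1.0 / (10.0 * s), 1.0)
    return -2.0 * np.log(surv)


def empirical_browns(data: np.ndarray, pvalues: Sequence[float]) -> float:
    """Combine k dependent p-values given the raw k x s data behind them.

    Each data row is transformed to its -2 ln (empirical survival) surrogate;
    the sample covariance of the surrogates inflates the variance of the
    Fisher statistic Omega = sum(-2 ln p). A scaled chi-square with
    moment-matched scale c = V/(2E) and df f = 2E^2/V gives the combined
    p-value as its upper tail at Omega/c. Degenerate (V <= 0) covariance
    falls back to Fisher's method with a warning.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    p = np.asarray(pvalues, dtype=float)
    k = p.size
    if k == 0:
        raise ValueError("empirical_browns requires at least one p-value")
    if data.shape[0] != k:
        raise ValueError("data rows must align with pvalues")
    omega = float(-2.0 * np.log(np.clip(p, 1e-300, 1.0)).sum())
    expected = 2.0 * k
    if k == 1:
        variance = 4.0 * k
    else:
        w = np.vstack([_ebm_transform(row) for row in data])
        cov = np.cov(w)
        variance = 4.0 * k + 2.0 * float(np.triu(cov, 1).sum())
    if variance <= 0:
        logger.warning("EBM variance <= 0; falling back to Fisher's method")
        variance = 4.0 * k
    c = variance / (2.0 * expected)
    f = 2.0 * expected**2 / variance
    return float(stats.chi2.sf(omega / c, f))


def fishers_method(pvalues: Sequence[float]) -> float:
    """Fisher's combination assuming independence (chi-square, 2k df)."""
    p = np.clip(np.asarray(pvalues, dtype=float), 1e-300, 1.0)
    return float(stats.chi2.sf(-2.0 * np.log(p).sum(), 2 * p.size))


# ---------------------------------------------------------------------------
# Global / pathway combination pipeline
# ---------------------------------------------------------------------------


def expression_kw_pvalues(
    matrix: FeatureMatrix, expression: pd.DataFrame
) -> pd.DataFrame:
    """Kruskal–Wallis p-value for every (feature, expression gene) pair.

    ``expression`` is genes x samples; only shared samples are used. Returns
    a features x genes DataFrame (nan where a group was empty).
    """
    common = [s for s in matrix.samples if s in expression.columns]
    if not common:
        raise ValueError("no shared samples between feature matrix and expression")
    vals = matrix.values.loc[common]
    expr = expression[common]
    out = pd.DataFrame(index=matrix.features, columns=expr.index, dtype=float)
    for f in matrix.features:
        fv = vals[f].to_numpy()
        for g in expr.index:
            out.loc[f, g] = kruskal_wallis(fv, expr.loc[g].to_numpy())
    return out


def combine_global_and_pathways(
    kw_pvalues: pd.DataFrame,
    expression: pd.DataFrame,
    pathways: Mapping[str, Sequence[str]],
    samples: Sequence[str] | None = None,
    fdr_levels: Sequence[float] = DEFAULT_FDR_LEVELS,
) -> tuple[list[AssociationResult], list[AssociationResult]]:
    """EBM-combine per-gene expression associations globally and per pathway.

    For each feature (row of ``kw_pvalues``) one GLOBAL combined p-value is
    computed over all measured expression genes, and one combined p-value per
    pathway over its measured members. BH correction is applied to global and
    pathway associations separately. Pathways with no measured member are
    skipped (logged).
    """
    if samples is not None:
        expression = expression[[s for s in samples if s in expression.columns]]
    genes = [g for g in kw_pvalues.columns if g in expression.index]
    global_results: list[AssociationResult] = []
    pathway_results: list[AssociationResult] = []
    for f in kw_pvalues.index:
        row = kw_pvalues.loc[f, genes].astype(float)
        valid = [g for g in genes if np.isfinite(row[g])]
        if not valid:
            continue
        data = expression.loc[valid].to_numpy()
        p = empirical_browns(data, row[valid].to_numpy())
        global_results.append(
            AssociationResult(feature_id=str(f), target="GLOBAL", p_value=p, kind="global")
        )
        for name, members in pathways.items():
            members_here = [g for g in members if g in valid]
            if not members_here:
                logger.info("pathway %s has no measured members; skipped", name)
                continue
            pp = empirical_browns(
                expression.loc[members_here].to_numpy(),
                row[members_here].to_numpy(),
            )
            pathway_results.append(
                AssociationResult(feature_id=str(f), target=name, p_value=pp, kind="pathway")
            )
    _apply_bh(global_results, fdr_levels)
    _apply_bh(pathway_results, fdr_levels)
    return global_results, pathway_results


# ---------------------------------------------------------------------------
# BH-FDR
# ---------------------------------------------------------------------------


def bh_fdr(pvalues: Sequence[float], q: float) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection flags at level ``q``.

    NaN p-values are never rejected and do not enter the correction.
    """
    p = np.asarray(pvalues, dtype=float)
    flags = np.zeros(p.size, dtype=bool)
    ok = np.isfinite(p)
    if ok.any():
        flags[ok] = multipletests(p[ok], alpha=q, method="fdr_bh")[0]
    return flags


# ---------------------------------------------------------------------------
# Direction calls
# ---------------------------------------------------------------------------


def direction_calls(
    feature: np.ndarray,
    expression: pd.DataFrame,
    pathway_genes: Sequence[str],
    kw_pvalues: Mapping[str, float] | None = None,
    q: float = 0.01,
) -> dict[str, Direction]:
    """Per-gene up/down calls for a pathway's significant members.

    Per-gene Kruskal–Wallis p-values (recomputed unless supplied) are
    BH-corrected within the pathway at FDR ``q``; the direction of each
    significant gene is the sign of mean(mutated) - mean(wild-type).
    Zero-variance genes are NA.
    """
    feature = np.asarray(feature)
    members = [g for g in pathway_genes if g in expression.index]
    ps = []
    for g in members:
        if kw_pvalues is not None and g in kw_pvalues:
            ps.append(kw_pvalues[g])
        else:
            ps.append(kruskal_wallis(feature, expression.loc[g].to_numpy()))
    flags = bh_fdr(np.array(ps, dtype=float), q)
    calls: dict[str, Direction] = {}
    for g, sig in zip(members, flags):
        if not sig:
            continue
        vals = expression.loc[g].to_numpy(dtype=float)
        if np.nanstd(vals) == 0:
            calls[g] = Direction.NA
            continue
        diff = np.nanmean(vals[feature == 1]) - np.nanmean(vals[feature == 0])
        calls[g] = Direction.UP if diff > 0 else Direction.DOWN
    return calls


# ---------------------------------------------------------------------------
# Drug response
# ---------------------------------------------------------------------------


def drug_associations(
    features: pd.DataFrame,
    ic50: pd.DataFrame,
    min_positives: int = 5,
    fdr: float = 0.10,
) -> list[AssociationResult]:
    """Kruskal–Wallis association of binary mutation features with drug
    ln-IC50 across cell lines.

    ``features`` is cell_line x feature (binary), ``ic50`` cell_line x drug
    with NaN for unscreened pairs; missing IC50s are dropped per drug, never
    imputed. Features with fewer than ``min_positives`` ones are discarded.
    BH at FDR ``fdr`` across all (feature, drug) pairs. Direction DOWN means
    mutated lines have lower ln-IC50 (more sensitive).
    """
    lines = [c for c in features.index if c in ic50.index]
    feats = features.loc[lines]
    resp = ic50.loc[lines]
    results: list[AssociationResult] = []
    for f in feats.columns:
        fv = feats[f].to_numpy()
        if fv.sum() < min_positives:
            continue
        for drug in resp.columns:
            y = resp[drug].to_numpy(dtype=float)
            if np.isfinite(y).sum() < 2:
                logger.info("drug %s has <2 usable IC50s; skipped", drug)
                continue
            p = kruskal_wallis(fv, y)
            if np.isnan(p):
                continue
            ok = np.isfinite(y)
            diff = np.nanmean(y[ok & (fv == 1)]) - np.nanmean(y[ok & (fv == 0)])
            results.append(
                AssociationResult(
                    feature_id=str(f),
                    target=str(drug),
                    p_value=p,
                    kind="drug",
                    direction=Direction.DOWN if diff < 0 else Direction.UP,
                )
            )
    _apply_bh(results, (fdr,))
    return results


def cellline_cluster_enrichment(
    gene_length: int,
    mutation_positions: Sequence[int],
    clusters: Sequence[Cluster],
    min_mutations: int = 10,
) -> float:
    """One-sided binomial test for cell-line mutations piling into clusters.

    Success probability is the fraction of the protein covered by clusters;
    the test asks whether the observed in-cluster count is larger than that
    uniform expectation. Genes with fewer than ``min_mutations`` mutations or
    no clusters are uninformative (p = 1).
    """
    pos = np.asarray(mutation_positions, dtype=int)
    if pos.size < min_mutations or not clusters:
        return 1.0
    covered = np.zeros(gene_length + 1, dtype=bool)
    for c in clusters:
        covered[c.start : c.end + 1] = True
    coverage = covered[1:].sum() / gene_length
    if coverage >= 1.0:
        return 1.0
    k = int(covered[pos].sum())
    return float(stats.binomtest(k, pos.size, coverage, alternative="greater").pvalue)
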