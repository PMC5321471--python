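"""Binary mutation features per tumor type and in-cluster coverage statistics.

For each tumor type, samples become rows of a binary matrix with one column
per cluster (1 if the sample carries a non-synonymous mutation inside the
cluster interval), one ``gene:ANY`` column per gene (any non-synonymous
mutation in the gene, inside or outside clusters) and one ``gene:OUTSIDE``
column (a non-synonymous mutation at a position covered by no cluster of the
gene). Cluster columns are by construction subsets of the ANY column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .mutation_data import Cluster, GeneTable

logger = logging.getLogger(__name__)

MIN_FEATURE_POSITIVES = 5


@dataclass
class FeatureMatrix:
    """Samples x binary features for one tumor type (or ``pan``)."""

    tumor_type: str
    values: pd.DataFrame  # index = sample IDs, columns = feature IDs, 0/1 ints

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    def positives(self, feature_id: str) -> int:
        return int(self.values[feature_id].sum())

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="sample")


def assign_features(
    gene_tables: Iterable[GeneTable],
    clusters: Sequence[Cluster],
    tumor_type: str,
    samples: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Project mutation data onto cluster/ANY/OUTSIDE binary features.

    ``tumor_type`` selects the records used (``"pan"`` uses all). The sample
    universe defaults to the samples observed for that tumor type; pass
    ``samples`` to include unmutated samples as all-zero rows. A sample with
    only synonymous mutations is 0 everywhere (wild-type). Interval
    membership is closed on both bounds.
    """
    tables = list(gene_tables)
    by_gene: dict[str, list[Cluster]] = {}
    for c in clusters:
        by_gene.setdefault(c.gene, []).append(c)

    records = [
        r
        for t in tables
        for r in t.records
        if tumor_type == "pan" or r.tumor_type == tumor_type
    ]
    if samples is None:
        sample_list = sorted({r.sample_id for r in records})
        if not sample_list:
            logger.warning("no samples for tumor type %r", tumor_type)
    else:
        sample_list = list(samples)

    feature_ids: list[str] = []
    for t in tables:
        for c in sorted(by_gene.get(t.gene, []), key=lambda c: c.start):
            feature_ids.append(c.feature_id)
        feature_ids.append(f"{t.gene}:ANY")
        feature_ids.append(f"{t.gene}:OUTSIDE")

    values = pd.DataFrame(
        0, index=sample_list, columns=feature_ids, dtype=int
    )
    sample_set = set(sample_list)
    for t in tables:
        gene_clusters = by_gene.get(t.gene, [])
        for r in t.records:
            if not r.non_synonymous or r.sample_id not in sample_set:
                continue
            if tumor_type != "pan" and r.tumor_type != tumor_type:
                continue
            values.loc[r.sample_id, f"{t.gene}:ANY"] = 1
            hit = False
            for c in gene_clusters:
                if c.start <= r.position <= c.end:
                    values.loc[r.sample_id, c.feature_id] = 1
                    hit = True
            if not hit:
                values.loc[r.sample_id, f"{t.gene}:OUTSIDE"] = 1
    return FeatureMatrix(tumor_type=tumor_type, values=values)


def filter_low_count(
    matrix: FeatureMatrix, min_positives: int = MIN_FEATURE_POSITIVES
) -> FeatureMatrix:
    """Drop features with fewer than ``min_positives`` positive samples,
    preserving column order."""
    keep = [f for f in matrix.features if matrix.values[f].sum() >= min_positives]
    return FeatureMatrix(tumor_type=matrix.tumor_type, values=matrix.values[keep])


def coverage_stats(
    gene_tables: Iterable[GeneTable],
    clusters: Sequence[Cluster],
    tumor_type: str = "pan",
) -> tuple[float, float, float]:
    """In-cluster mutation concentration for one tumor type (or ``pan``).

    Returns ``(pct_nonsyn_in_clusters, pct_sequence_covered, ratio)``:

    * numerator — percent of the tumor type's non-synonymous mutations (in
      genes that have clusters) falling inside any cluster;
    * denominator — percent of the summed protein length of those genes
      covered by clusters that contain at least one of the tumor type's
      non-synonymous mutations;
    * ratio — numerator / denominator, ``nan`` when the denominator is 0.

    A ratio of 1 means mutations are spread as uniformly over cluster
    sequence as over the rest; larger values mean clusters concentrate
    mutations.
    """
    by_gene: dict[str, list[Cluster]] = {}
    for c in clusters:
        by_gene.setdefault(c.gene, []).append(c)

    total_nonsyn = 0
    in_cluster = 0
    total_length = 0
    covered_length = 0
    for t in gene_tables:
        gene_clusters = by_gene.get(t.gene, [])
        if not gene_clusters:
            continue
        total_length += t.length_aa
        positions = np.array(
            [
                r.position
                for r in t.records
                if r.non_synonymous
                and (tumor_type == "pan" or r.tumor_type == tumor_type)
            ],
            dtype=int,
        )
        total_nonsyn += positions.size
        covered = np.zeros(positions.size, dtype=bool)
        for c in gene_clusters:
            inside = (positions >= c.start) & (positions <= c.end)
            covered |= inside
            if inside.any():
                covered_length += c.length
        in_cluster += int(covered.sum())

    pct_in = 100.0 * in_cluster / total_nonsyn if total_nonsyn else float("nan")
    pct_cov = 100.0 * covered_length / total_length if total_length else float("nan")
    ratio = pct_in / pct_cov if pct_cov and np.isfinite(pct_cov) else float("nan")
    return pct_in, pct_cov, ratio
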