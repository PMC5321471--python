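import numpy as np
import pytest

import mutclust as mc


@pytest.fixture
def two_cluster_spec() -> mc.SyntheticSpec:
    """Two well-separated planted clusters over a moderate uniform background."""
    return mc.SyntheticSpec(
        gene="GENE1",
        length_aa=500,
        clusters=(
            mc.PlantedCluster(mu=150, sigma=3, count=60),
            mc.PlantedCluster(mu=350, sigma=4, count=60),
        ),
        background=80,
        synonymous_fraction=0.1,
        tumor_types=("BRCA", "UCEC"),
        samples_per_type=200,
        seed=5,
    )


@pytest.fixture
def two_cluster_table(two_cluster_spec) -> mc.GeneTable:
    return mc.generate_synthetic_gene(two_cluster_spec)


@pytest.fixture
def two_cluster_clusters(two_cluster_table) -> list[mc.Cluster]:
    return mc.find_clusters(two_cluster_table)


def make_gene_table(gene: str, entries, length_aa: int | None = None) -> mc.GeneTable:
    """Build a GeneTable from (sample, tumor_type, position, variant_class) tuples."""
    records = [
        mc.MutationRecord(
            gene=gene,
            sample_id=s,
            tumor_type=tt,
            position=pos,
            variant_class=mc.VariantClass(vc) if isinstance(vc, str) else vc,
        )
        for s, tt, pos, vc in entries
    ]
    L = length_aa or max(r.position for r in records)
    return mc.GeneTable(gene=gene, length_aa=L, records=records)


def random_candidate_pool(rng: np.random.Generator, n: int, L: int = 300):
    """Random candidate clusters for merge-algorithm tests."""
    pool = []
    for _ in range(n):
        start = int(rng.integers(1, L - 30))
        width = int(rng.integers(5, 60))
        end = min(start + width, L)
        mu = (start + end) / 2 + rng.normal(0, 2)
        sigma = max(1.0, width / 4 + rng.normal(0, 1))
        pool.append(
            mc.Candidate(
                start=start,
                end=end,
                mu=float(mu),
                sigma=float(sigma),
                weight=0.2,
                n_mutations=int(rng.integers(15, 60)),
                bandwidth=float(rng.choice([2.0, 10.0, 50.0])),
            )
        )
    return pool
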