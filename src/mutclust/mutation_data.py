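"""Domain types, table readers/writers and the synthetic-data generator.

Somatic mutations are represented in amino-acid space: each record is one
mutation event in one tumor sample, located at a 1-based residue position of
a protein. Variant classes collapse to three categories: ``synonymous``
(silent), ``missense``, and ``nonsense_like`` (frameshift, in-frame indel,
stop gain/loss, splice) — the protein-truncating / disruptive group.
Non-synonymous means missense or nonsense_like.

The synthetic generator plants Gaussian mutation clusters on top of a uniform
background so that every downstream module (density estimation, mixture
fitting, multiscale merging, feature assignment, association statistics) can
be exercised without external data.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class VariantClass(enum.Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE_LIKE = "nonsense_like"


#: Mapping from common MAF-style variant classification strings to the
#: three-way vocabulary. Anything absent from this table and not recognised
#: as silent is treated as missense (protein-altering, non-truncating).
VARIANT_CLASS_MAP: dict[str, VariantClass] = {
    "synonymous": VariantClass.SYNONYMOUS,
    "silent": VariantClass.SYNONYMOUS,
    "synonymous_variant": VariantClass.SYNONYMOUS,
    "missense": VariantClass.MISSENSE,
    "missense_mutation": VariantClass.MISSENSE,
    "missense_variant": VariantClass.MISSENSE,
    "nonsense_like": VariantClass.NONSENSE_LIKE,
    "nonsense": VariantClass.NONSENSE_LIKE,
    "nonsense_mutation": VariantClass.NONSENSE_LIKE,
    "nonstop_mutation": VariantClass.NONSENSE_LIKE,
    "stop_gained": VariantClass.NONSENSE_LIKE,
    "stop_lost": VariantClass.NONSENSE_LIKE,
    "frame_shift_del": VariantClass.NONSENSE_LIKE,
    "frame_shift_ins": VariantClass.NONSENSE_LIKE,
    "frameshift": VariantClass.NONSENSE_LIKE,
    "frameshift_variant": VariantClass.NONSENSE_LIKE,
    "in_frame_del": VariantClass.NONSENSE_LIKE,
    "in_frame_ins": VariantClass.NONSENSE_LIKE,
    "indel": VariantClass.NONSENSE_LIKE,
    "splice_site": VariantClass.NONSENSE_LIKE,
    "splice": VariantClass.NONSENSE_LIKE,
}

#: The 23 tumor-type codes of the pan-cancer study design.
TUMOR_TYPES: tuple[str, ...] = (
    "ACC", "BLCA", "BRCA", "CESC", "COAD", "GBM", "HNSC", "KICH", "KIRC",
    "KIRP", "LAML", "LGG", "LIHC", "LUAD", "LUSC", "OV", "PRAD", "READ",
    "SKCM", "STAD", "THCA", "UCEC", "UCS",
)


class FormatError(ValueError):
    """Raised when an input table does not match the expected layout."""


def parse_variant_class(label: str | VariantClass) -> VariantClass:
    """Map a free-form variant classification string to the 3-way enum.

    Unrecognised, non-silent labels default to missense (protein-altering).
    """
    if isinstance(label, VariantClass):
        return label
    key = str(label).strip().lower()
    if key in VARIANT_CLASS_MAP:
        return VARIANT_CLASS_MAP[key]
    return VariantClass.MISSENSE


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation event at an amino-acid position (1-based)."""

    gene: str
    sample_id: str
    tumor_type: str
    position: int
    variant_class: VariantClass

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")

    @property
    def non_synonymous(self) -> bool:
        return self.variant_class is not VariantClass.SYNONYMOUS


@dataclass
class GeneTable:
    """All mutation records of one gene plus its protein length L."""

    gene: str
    length_aa: int
    records: list[MutationRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for r in self.records:
            if r.gene != self.gene:
                raise ValueError(f"record gene {r.gene!r} != table gene {self.gene!r}")
        max_pos = max((r.position for r in self.records), default=1)
        if self.length_aa < max_pos:
            raise ValueError(
                f"{self.gene}: length_aa={self.length_aa} < max position {max_pos}"
            )

    @property
    def positions(self) -> np.ndarray:
        """All mutation positions (any class), as an int array."""
        return np.array([r.position for r in self.records], dtype=int)

    @property
    def nonsyn_positions(self) -> np.ndarray:
        return np.array(
            [r.position for r in self.records if r.non_synonymous], dtype=int
        )

    @property
    def synonymous_fraction(self) -> float:
        """Fraction of records that are synonymous; 0 when the table is empty."""
        if not self.records:
            return 0.0
        n_syn = sum(not r.non_synonymous for r in self.records)
        return n_syn / len(self.records)


@dataclass(frozen=True)
class Cluster:
    """A closed amino-acid interval with its generating Gaussian and score."""

    gene: str
    start: int
    end: int
    mu: float
    sigma: float
    weight: float
    n_mutations: int
    score: float
    bandwidth: float | None = None  # source scale; None once merged/read back

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def feature_id(self) -> str:
        return f"{self.gene}:{self.start}-{self.end}"

    def overlaps(self, other: "Cluster") -> bool:
        return self.gene == other.gene and not (
            self.end < other.start or other.end < self.start
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("gene", "sample", "tumor_type", "position", "variant_class")


def read_gene_lengths(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV (gene, length_aa) into a dict."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "length_aa"):
        if col not in df.columns:
            raise FormatError(f"gene-lengths file missing required column {col!r}")
    return dict(zip(df["gene"].astype(str), df["length_aa"].astype(int)))


def read_mutation_table(
    path: str | Path, lengths: Mapping[str, int] | None = None
) -> list[GeneTable]:
    """Read a mutation TSV into per-gene tables.

    The file must carry a header with at least the columns
    ``gene, sample, tumor_type, position, variant_class``. Positions are
    1-based amino-acid coordinates. When no length is registered for a gene
    the protein length falls back to the maximum observed position.

    Raises
    ------
    FormatError
        If a required column is missing, or a position fails to parse as an
        integer (the error names the offending line).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"mutation table missing required column {col!r}")
    positions = pd.to_numeric(df["position"], errors="coerce")
    bad = positions.isna() & df["position"].notna()
    if bad.any() or positions.isna().any():
        line = int(np.flatnonzero(positions.isna().to_numpy())[0]) + 2  # header + 1-based
        raise FormatError(f"non-integer position at line {line}")
    tables: list[GeneTable] = []
    for gene, sub in df.groupby("gene", sort=True):
        records = [
            MutationRecord(
                gene=str(gene),
                sample_id=str(row["sample"]),
                tumor_type=str(row["tumor_type"]),
                position=int(float(row["position"])),
                variant_class=parse_variant_class(row["variant_class"]),
            )
            for _, row in sub.iterrows()
        ]
        max_pos = max(r.position for r in records)
        length = int(lengths[gene]) if lengths and gene in lengths else max_pos
        tables.append(GeneTable(gene=str(gene), length_aa=length, records=records))
    return tables


def write_mutation_table(tables: Iterable[GeneTable], path: str | Path) -> None:
    """Inverse of :func:`read_mutation_table` (gene lengths are not stored)."""
    rows = [
        {
            "gene": r.gene,
            "sample": r.sample_id,
            "tumor_type": r.tumor_type,
            "position": r.position,
            "variant_class": r.variant_class.value,
        }
        for t in tables
        for r in t.records
    ]
    pd.DataFrame(
        rows, columns=["gene", "sample", "tumor_type", "position", "variant_class"]
    ).to_csv(path, sep="\t", index=False)


_CLUSTER_COLUMNS = ("gene", "start", "end", "n_mutations", "score", "mu", "sigma", "weight")


def write_clusters(clusters: Sequence[Cluster], path: str | Path) -> None:
    """Write clusters as a BED-like TSV (1-based, closed intervals).

    Raises
    ------
    ValueError
        If two clusters of the same gene overlap.
    """
    by_gene: dict[str, list[Cluster]] = {}
    for c in clusters:
        by_gene.setdefault(c.gene, []).append(c)
    for gene, cs in by_gene.items():
        cs_sorted = sorted(cs, key=lambda c: c.start)
        for a, b in zip(cs_sorted, cs_sorted[1:]):
            if a.overlaps(b):
                raise ValueError(
                    f"overlapping clusters in {gene}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
    pd.DataFrame(
        [
            {
                "gene": c.gene,
                "start": c.start,
                "end": c.end,
                "n_mutations": c.n_mutations,
                "score": c.score,
                "mu": c.mu,
                "sigma": c.sigma,
                "weight": c.weight,
            }
            for c in clusters
        ],
        columns=_CLUSTER_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_clusters(path: str | Path) -> list[Cluster]:
    """Read a cluster TSV written by :func:`write_clusters`."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "start", "end"):
        if col not in df.columns:
            raise FormatError(f"cluster table missing required column {col!r}")
    out = []
    for _, row in df.iterrows():
        out.append(
            Cluster(
                gene=str(row["gene"]),
                start=int(row["start"]),
                end=int(row["end"]),
                mu=float(row.get("mu", (row["start"] + row["end"]) / 2)),
                sigma=float(row.get("sigma", max(1.0, (row["end"] - row["start"] + 1) / 4))),
                weight=float(row.get("weight", 1.0)),
                n_mutations=int(row.get("n_mutations", 0)),
                score=float(row.get("score", 0.0)),
            )
        )
    return out


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read pathway membership lists in GMT format (name, description, genes...)."""
    pathways: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            pathways[parts[0]] = [g for g in parts[2:] if g]
    return pathways


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read an expression TSV (rows = genes, columns = samples) -> genes x samples."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_drug_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format drug table (cell_line, drug, ln_ic50; blank = missing).

    Returns a cell_line x drug matrix of natural-log IC50 values with NaN for
    unscreened pairs.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("cell_line", "drug", "ln_ic50"):
        if col not in df.columns:
            raise FormatError(f"drug table missing required column {col!r}")
    return df.pivot_table(index="cell_line", columns="drug", values="ln_ic50")


# ---------------------------------------------------------------------------
# Synthetic data generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedCluster:
    """A Gaussian mutation cluster to plant: center mu, width sigma, count."""

    mu: float
    sigma: float
    count: int

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("planted cluster sigma must be > 0")
        if self.count < 0:
            raise ValueError("planted cluster count must be >= 0")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic gene: planted clusters over uniform background.

    ``synonymous_fraction`` of all records (chosen at random, irrespective of
    origin) are relabelled synonymous; the rest are split between missense and
    nonsense_like. ``tumor_types`` and ``samples_per_type`` define the sample
    universe records are attributed to.
    """

    gene: str = "GENE1"
    length_aa: int = 500
    clusters: tuple[PlantedCluster, ...] = ()
    background: int = 0
    synonymous_fraction: float = 0.1
    nonsense_fraction: float = 0.25  # of the non-synonymous records
    tumor_types: tuple[str, ...] = ("BRCA",)
    samples_per_type: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background < 0:
            raise ValueError("background count must be >= 0")
        if not 0 <= self.synonymous_fraction < 1:
            raise ValueError("synonymous_fraction must be in [0, 1)")
        for c in self.clusters:
            if not 1 <= c.mu <= self.length_aa:
                raise ValueError(f"cluster center {c.mu} outside [1, {self.length_aa}]")

    @property
    def total_count(self) -> int:
        return self.background + sum(c.count for c in self.clusters)


def generate_synthetic_gene(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> GeneTable:
    """Draw one gene's mutation table from a :class:`SyntheticSpec`.

    Cluster positions are Gaussian draws rounded and clipped to ``[1, L]``;
    background positions are uniform integers on ``[1, L]``. Sample IDs are
    assigned uniformly at random from the configured sample universe, and
    tumor types proportionally to that universe. Reproducible given the seed.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    L = spec.length_aa
    positions: list[int] = []
    for pc in spec.clusters:
        draws = rng.normal(pc.mu, pc.sigma, size=pc.count)
        positions.extend(int(p) for p in np.clip(np.rint(draws), 1, L))
    positions.extend(int(p) for p in rng.integers(1, L + 1, size=spec.background))

    n = len(positions)
    classes = np.array([VariantClass.MISSENSE] * n, dtype=object)
    n_syn = int(round(spec.synonymous_fraction * n))
    idx = rng.permutation(n)
    classes[idx[:n_syn]] = VariantClass.SYNONYMOUS
    nonsyn_idx = idx[n_syn:]
    n_nonsense = int(round(spec.nonsense_fraction * len(nonsyn_idx)))
    classes[nonsyn_idx[:n_nonsense]] = VariantClass.NONSENSE_LIKE

    sample_pool = [
        f"{tt}-S{j:04d}"
        for tt in spec.tumor_types
        for j in range(spec.samples_per_type)
    ]
    tt_of = {s: s.split("-S")[0] for s in sample_pool}
    chosen = rng.choice(len(sample_pool), size=n) if n else np.array([], dtype=int)
    records = [
        MutationRecord(
            gene=spec.gene,
            sample_id=sample_pool[chosen[i]],
            tumor_type=tt_of[sample_pool[chosen[i]]],
            position=positions[i],
            variant_class=classes[i],
        )
        for i in range(n)
    ]
    return GeneTable(gene=spec.gene, length_aa=L, records=records)


def generate_expression_matrix(
    genes: Sequence[str],
    samples: Sequence[str],
    mutated_samples: Mapping[str, Sequence[str]] | None = None,
    shift: float = 0.0,
    correlation: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a genes x samples expression matrix.

    Baseline expression is standard normal with a shared latent factor giving
    pairwise inter-gene correlation ``correlation``. For each gene listed in
    ``mutated_samples``, the given samples get an additive mean ``shift``
    (in SD units) — the planted mutation -> expression effect.
    """
    if not 0 <= correlation < 1:
        raise ValueError("correlation must be in [0, 1)")
    rng = np.random.default_rng(seed)
    g, s = len(genes), len(samples)
    latent = rng.normal(size=s)
    noise = rng.normal(size=(g, s))
    x = np.sqrt(correlation) * latent[None, :] + np.sqrt(1 - correlation) * noise
    df = pd.DataFrame(x, index=list(genes), columns=list(samples))
    if mutated_samples:
        for gene, mut in mutated_samples.items():
            if gene in df.index:
                cols = [c for c in mut if c in df.columns]
                df.loc[gene, cols] += shift
    return df


def generate_drug_response(
    cell_lines: Sequence[str],
    drugs: Sequence[str],
    sensitive: Mapping[str, Sequence[str]] | None = None,
    effect: float = 0.0,
    missing_fraction: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a cell_line x drug ln-IC50 matrix with optional missingness.

    ``sensitive`` maps drug -> cell lines whose ln-IC50 is lowered by
    ``effect`` (SD units); entries are masked to NaN independently with
    probability ``missing_fraction``.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(len(cell_lines), len(drugs)))
    df = pd.DataFrame(x, index=list(cell_lines), columns=list(drugs))
    if sensitive:
        for drug, lines in sensitive.items():
            if drug in df.columns:
                rows = [c for c in lines if c in df.index]
                df.loc[rows, drug] -= effect
    if missing_fraction > 0:
        mask = rng.random(df.shape) < missing_fraction
        df = df.mask(mask)
    return df


def subset_gene_table(table: GeneTable, sample_ids: set[str]) -> GeneTable:
    """Restrict a gene table to records from the given samples."""
    return replace(
        table, records=[r for r in table.records if r.sample_id in sample_ids]
    )
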