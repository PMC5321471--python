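# Methods

## Model

Mutation positions of one gene are modelled as i.i.d. draws from a mixture
over the discrete positions 1..L (L = protein length in amino acids):

p(x) = Σ_k w_k · G(x; μ_k, σ_k) + w₀ / L

with n Gaussian cluster components and one uniform background component
whose support is fixed to the gene. Weights sum to one. The uniform
component represents passenger mutations with no positional preference; the
Gaussians represent mutation clusters. All coordinates are 1-based and
cluster intervals are closed on both ends, so an interval 539–547 includes
both boundary residues and a single-residue hotspot has start = end.

### Multi-bandwidth seeding

The number of clusters and their initial parameters are not chosen by the
user; they come from kernel density estimates of the mutation positions at
28 bandwidths spanning 2–450 amino acids. Only the count and the range of
the grid are fixed by the study design; the spacing is a free choice, and
log-spacing was picked because the scales span two orders of magnitude —
linear spacing would waste most of the grid on domain-sized bandwidths and
resolve single-residue structure poorly.

The KDE is evaluated on the integer grid with unit step and no boundary
reflection; mass smoothed past the gene ends is truncated (verified in
tests to cost < 1% of the non-truncated mass at every bandwidth). Each
interior local maximum of a density seeds one Gaussian: the mean at the
maximum, the standard deviation equal to the distance between the two
flanking local minima (gene termini count as minima when no interior
minimum exists on a side), and the raw weight equal to the density at the
maximum minus 1/n-th of the noise weight, floored at 10⁻⁶ so no component
enters EM with zero mass. The noise weight starts at the gene's synonymous
mutation fraction — synonymous mutations carry no selective signal, so
their share is a natural prior for the background. Gaussian weights are
then scaled to fill exactly 1 − noise, which keeps the seeded noise weight
at the synonymous fraction rather than diluting it.

### EM refinement

Standard EM with responsibilities over the n + 1 components. The uniform
component's support is fixed; only its weight updates. Convergence is an
absolute log-likelihood gain below 10⁻⁶ or 500 iterations; σ is floored at
0.5 aa to prevent singular components on single-residue hotspots. A
component whose weight collapses below 10⁻⁶ is removed and EM restarts once
with the survivors. Responsibility ties break toward the lower component
index, making the output deterministic. Per-iteration monotonicity of the
log-likelihood is asserted in the test suite.

### Candidate intervals and the ≥15-mutation cutoff

Clusters are conventionally reported as position pairs x–y, which leaves
the mapping from a fitted Gaussian to an interval open. Here a
component's interval is the [min, max] of the mutation positions whose
maximum responsibility falls on that component; a component with no
assigned mutations is dropped. This reproduces the observed phenomenology
(length-1 clusters, integer bounds) without inventing a width convention.
A candidate must hold at least 15 mutations (all variant classes, counted
on the extracted interval, i.e. after EM refinement) to enter the merge.

### Multiscale merge

Candidates from all 28 scales are placed in a binary tree by agglomerative
clustering (single linkage) on the unsigned area between their unit-mass
Gaussian curves, ∫|φ₁ − φ₂|dx ∈ [0, 2], computed by adaptive quadrature.
The tree is flattened bottom-up. At each internal node the two children's
cluster sets are merged by choosing, among the *maximal* non-overlapping
subsets of their union, the one minimizing AICc; each node carries the best
4 near-tied selections upward (a small beam). The root re-optimizes over
all non-overlapping subsets, where candidates may also be dropped outright
— a gene can come out with no clusters at all (pure background). Restricting
interior nodes to maximal subsets matters: a genuine cluster can look
AICc-negative *alone*, because mutations elsewhere in the gene pay the
noise-weight dilution, and dropping it early is unrecoverable. Finally the
result is compared against every single-bandwidth candidate set and
replaced if one scores lower, so the multiscale answer is never worse than
any individual scale (a hard invariant of the implementation).

The AICc of a selection is computed on the mixture holding the selected
Gaussians plus the uniform component, with weights re-fit by one EM pass
(means and σ fixed at their per-scale values) and

AICc = −2·logL + 2k + 2k(k+1)/(n−k−1),  k = 3·(#Gaussians) + 1

(μ, σ, w per Gaussian, plus the noise weight, minus the sum-to-one
constraint). n ≤ k+1 yields +∞ so selection avoids over-parameterization.
Subset searches are exhaustive up to 12 candidates per node union and fall
back to greedy forward selection beyond that; AICc ties prefer fewer
clusters, then smaller total interval length, then lexicographic order, so
output is deterministic. Non-overlap is defined on the extracted intervals,
not on Gaussian supports.

### Cluster score

S_c = Σᵢ log(G(Mᵢ; μ_c, σ_c)/U) over the mutations inside the interval,
U = 1/L. A mutation at the mean of a Gaussian with σ = L/√(2π) contributes
exactly zero — the Gaussian emits it no better than the background.

## Downstream statistics

*Feature assignment.* Per tumor type, a sample is positive for a cluster if
it carries a non-synonymous (missense or nonsense-like) mutation inside the
closed interval. `gene:ANY` records any non-synonymous mutation in the
gene, `gene:OUTSIDE` one at a position covered by no cluster; cluster
positivity implies ANY-positivity and ANY = cluster-positive OR
OUTSIDE-positive, both asserted as invariants. Features with fewer than 5
positive samples are excluded from association testing. Duplicate mutation
records are kept as distinct events; deduplication happens implicitly at
the sample level in the binary features.

*Coverage ratio.* The percent of non-synonymous mutations inside clusters
divided by the percent of protein sequence covered by clusters containing
at least one such mutation of the selected tumor type. Both percentages
pool over all genes that have clusters (a single cohort-level number, the
less ambiguous of the two readings of the published definition). The ratio
is 1 under uniform mutation placement (verified by simulation) and grows
with concentration.

*Enrichment.* Fisher's exact test on the 2×2 table of (mutated in cluster)
× (belongs to tumor type) over the pan-cancer sample universe, two-sided by
default (a one-sided alternative is a flag), BH-corrected across all
(cluster, tumor type) pairs at FDR 1/5/10/25%.

*Expression association.* Kruskal–Wallis (tie-corrected, χ² with 1 df for
two groups) between each binary feature and each expression target;
complete-case with respect to missing values. Per-feature combination with
the Empirical Brown's Method: each target's raw expression row is
transformed to w(s) = −2·ln F̂(x(s)) with F̂ the right-tail empirical
survival function (averaged ranks, clipped at 1/(10s) to keep logs finite);
the sample covariance of the transforms inflates the variance of the Fisher
statistic Ω = Σ −2 ln pᵢ, and a moment-matched scaled χ² (scale c = V/2E,
df f = 2E²/V, E = 2k) gives the combined p. When k = 1 or the empirical
covariances vanish this reduces exactly to Fisher's method; duplicated rows
collapse to the single p-value (both identities are tested). Degenerate
V ≤ 0 falls back to Fisher's method with a warning. The combination runs
once over all targets (the "global" association) and once per pathway over
its measured members; BH is applied to global and pathway families
separately. Expression values enter untransformed: the rank tests are
invariant to monotone transforms and the covariance estimate uses the data
as deposited.

*Direction calls.* Within a significant pathway, per-gene Kruskal–Wallis
p-values are BH-corrected at FDR 1% separately per pathway; each
significant gene is called up or down by the sign of mean(mutated) −
mean(wild-type). Zero-variance genes are NA.

*Drug response.* Kruskal–Wallis between binary cell-line mutation features
(≥5 positives) and per-drug ln-IC50 (natural log of the μM half-maximal
inhibitory concentration); missing IC50s are dropped per drug, never
imputed; BH at FDR 10% across all (feature, drug) pairs. Cell-line
in-cluster enrichment uses a one-sided binomial test with success
probability equal to the cluster-covered fraction of the protein, for genes
with ≥10 cell-line mutations — there is no single canonical statistic for
this step, so the binomial-coverage test is this package's documented
choice.

*Cross-validation.* Samples are split into two halves (sizes within 1),
re-drawn up to 200 times until non-synonymous and synonymous mutation
counts differ by at most 5% (relative) between halves; the best split is
returned with a warning if the tolerance is never met. The split is by
sample, since features are sample-level; stratification by tumor type is
available via a flag but off by default. A cluster is conserved when some
same-gene cluster of the other half covers it — or is covered by it — by
strictly more than 50% of interval length ("over 50%" read as strict, so a
10-aa cluster overlapped on exactly 5 positions is *not* conserved).
Generative validation evaluates each half's mixture on the other half's
positions and reports the Spearman correlation between the two directions.
Association robustness is the fraction of one half's significant
associations matched (same target, same or >50%-overlapping cluster) by a
significant association in the other half.

## Synthetic data

The generator plants Gaussian clusters (center, width, count) over a
uniform background on [1, L], rounds and clips draws to the grid, relabels
a configurable fraction of records as synonymous, splits the rest between
missense and nonsense-like, and attributes records to a configurable
sample/tumor-type universe. Expression matrices are standard normal with a
shared latent factor for inter-gene correlation and additive mean shifts in
mutated samples; drug-response matrices are standard normal ln-IC50 with
group shifts and independent missingness. What it does *not* emulate:
per-sample mutation-burden heterogeneity, trinucleotide mutation signatures,
gene-length-dependent background rates, copy-number context, or realistic
expression covariance structure beyond a single factor. Tests passing on
this generator therefore demonstrate algorithmic correctness and calibration
under the stated model, not robustness to every property of real cohorts.

## Problem sizes and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| bandwidth grid | 28 log-spaced on [2, 450] | aa | fixed count/range; log spacing spans the scales evenly |
| min mutations per cluster | 15 | events | candidate eligibility for the merge |
| min feature positives | 5 | samples | association-testing eligibility |
| EM tolerance / max iterations | 10⁻⁶ / 500 | logL / – | standard practice |
| σ floor | 0.5 | aa | prevents singular single-residue components |
| FDR levels | 1, 5, 10, 25 | % | reporting grid |
| exhaustive subset limit / beam | 12 / 4 | candidates | exact small-pool search, bounded node cost |
| split balance tolerance / retries | 5% / 200 | relative | partition comparability |

Simulation-based checks use synthetic genes of L = 400–600 with 2–4 planted
clusters of 30–130 mutations over ≤50% uniform background, 100 replicates
for recovery, 200 for the null-FDR calibration, 50 genes for the held-out
likelihood correlation, and 200 random pools (≤10 candidates) for the
greedy-versus-exhaustive comparison; the acceptance script runs the same
experiments at 40–100 replicates.

## Known limitations

- The merge is greedy: with the beam it matches exhaustive enumeration on
  >90% of small random pools, but global AICc optimality is not guaranteed
  (the bound against every single-scale model is).
- Interval extraction by responsibility argmax can, in principle, produce
  interleaved intervals at one scale; non-overlap is enforced only on the
  final set.
- The EBM survival-function clip (1/(10s)) biases very small combined
  p-values conservatively for tiny sample counts.
- Gene length defaults to the maximum observed mutation position when no
  lengths file is given, which inflates U = 1/L slightly and therefore
  deflates scores for genes whose C-terminus is unmutated.
- One-dimensional sequence clustering cannot see spatial proximity in the
  folded protein; clusters that are adjacent in 3D remain separate.
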