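# Methods

This note documents the models and numerical choices behind `looplink`:
what each stage computes, which parameters matter, and what the
synthetic ground truth does and does not establish about real data.

## Cross-link parsing and filtering

A cross-link identification is an unordered pair of residue positions
on one protein. The parser accepts any delimited table through a
column-name schema (search-engine dialects differ; the schema is YAML-
configurable, and residue-letter prefixes like `K190` are stripped).
Four filters apply, each with a logged count:

* **decoys** — identifications from the search engine's shuffled
  database, marked by a configurable cell value;
* **homeotypic links** — two copies of the same peptide cross-linked to
  each other. These witness inter-molecular dimer contacts, not
  intra-molecular structure. Since no universal definition exists in
  result tables, a record is treated as homeotypic when its two peptide
  spans overlap as residue intervals; without span columns the fallback
  is site equality.
* **inter-protein records** — the analysis is intra-molecular;
* **self-pairs** (`site_a == site_b`).

Duplicates of the same site pair are *kept* as multiplicities: the rate
at which a pair is re-observed reflects reaction-site accessibility and
feeds the observation-level subsampling below. Scores are passed
through; the optional minimum-score filter is off by default because
tables are assumed pre-filtered by the search engine's own statistics.

Site enumeration counts K/S/T/Y positions (the DSBU-reactive residues).
The theoretical pair maximum `n(n−1)/2` excludes self-pairs. The
N-terminus can optionally be counted as a site, but the default is off:
the bundled reference sequences reproduce the standard maxima from
K/S/T/Y alone (2N4R Tau: 129 sites → 8,256; horse myoglobin: 33 → 528).

## Structural networks and loops

The network over residues `1..L` has `L−1` backbone edges and one edge
per unique cross-link with `|i−j| ≥ 2`; sequence-adjacent pairs would
duplicate backbone edges and are dropped (logged). Multiplicity is an
edge attribute, never edge duplication — clustering and similarity
operate on the simple graph while duplicate counts stay available for
reporting. Three weight conventions: `uniform` (display: backbone 1,
cross-link 8), `linker_span` (backbone 3.8 Å, cross-links the 26–30 Å
DSBU midpoint, 28 Å), and `model_distance` (per-pair Cα distances from
a structure, falling back to the span midpoint for unmappable pairs).
Networks round-trip through GML with fixed attribute order
(type, weight, multiplicity).

Each cross-link `(i, j)` closes a cycle with the *backbone* shortest
path between its endpoints. The backbone subgraph is a path graph, so
that path is unique and the loop is exactly the interval `{i..j}`;
cross-link edges are never used as shortcuts inside another loop, which
keeps loops well-defined intervals. Nested and overlapping cross-links
simply yield nested and overlapping loops. Residues covered by no loop
become singleton clusters so that any two clusterings of the same
protein share one element universe — a requirement of the similarity
measure. One loop per *unique* cross-link edge, bijectively.

## Element-centric similarity

Let `k_i` be the number of clusters containing residue `i`. The
cluster-walk transition matrix is

    W[i,j] = (1/k_i) · Σ_{clusters c ∋ i,j} 1/|c|

(uniform choice over an element's clusters, then uniform over the
cluster's members — the standard extension of the element-centric
measure to overlapping clusterings; rows sum to 1). Residue `i`'s
affinity row solves the personalized random walk with restart,

    p_i = (1−α)·e_i + α·p_i·W,

and two clusterings A, B are compared per residue by

    S_i = 1 − (1/2α) · Σ_j |p^A_ij − p^B_ij|,   clipped to [0, 1].

`α` multiplies the cluster-walk term: α = 0.9 (default) weights cluster
structure heavily and so favours detection of subtle, localized
membership changes; the restart mass (1−α) guarantees the linear system
`p_i (I − αW) = (1−α) e_i` is strictly diagonally dominant and uniquely
solvable. For universes up to 500 elements the affinities come from a
dense direct solve; beyond that, power iteration with an L1 residual
tolerance of 1e-10 and a 10,000-iteration cap (the two agree to < 1e-8
on the tested sizes). Clipping below 0 can occur only for pathological
overlap patterns; it is counted and logged, and never fires on loop
clusterings in the test suite. For disjoint partitions the affinities
reduce to the closed form `p_ij = (1−α)δ_ij + α/|c|`, which the tests
use as an independent oracle.

Both a standard deviation and a normal-approximation 95% CI
(`mean ± 1.96·sd/√n_boot`) are reported wherever similarity is averaged
over draws; with the default `n_boot = 10`, percentile intervals would
be meaningless, hence the normal approximation.

## Replicate saturation and the random-sampling null

Empirical accumulation: replicate order is permuted uniformly per
cycle (default 84 cycles) and the cumulative count of distinct site
pairs recorded; the mean curve is reported, and every cycle necessarily
ends at the union size. The null model draws, per simulated replicate,
a fixed number of *distinct* pairs (default 100) uniformly from a fixed
pool of P possible pairs (a replicate's unique-link list has no
duplicates), averaged over 199 cycles by default. Its closed-form mean,
`E[U_k] = P(1 − (1 − m/P)^k)`, anchors the correctness tests.

## Subsample similarity and the divergence threshold

For each sample size m, m observations are drawn **without replacement
from the observation multiset** (duplicates count as separate
observations — sample-size statements include duplicates), collapsed to
unique pairs, rebuilt into a network, and compared by ECS; means, sds
and CIs are taken over `n_boot = 10` draws. A with-replacement bootstrap
mode exists behind a flag for sensitivity analysis. The intra-state
curve compares two independent subsamples of the same state, so at the
full sample size it equals exactly 1.

The divergence threshold is operationalized as the smallest grid size
from which, for all larger grid sizes, the inter-state CI upper bound
stays strictly below the intra-state CI lower bound. This CI-separation
rule is a design choice (no standard rule exists for "reliably detect");
it is deliberately conservative in requiring sustained separation.

## Leave-one-out influence

For each unique pair present in state A but not state B, that single
edge is removed from A's network, loops are re-extracted, and the
modified clustering is compared to both originals: deviation
`1 − ECS(modified, A)` and shift `ECS(modified, B) − ECS(A, B)`
(positive shift = the perturbed network moved *closer* to the other
state). Averages are reported in percent. The reference affinity
matrices are solved once and reused across removals, which makes the
full-study analysis (≈1,500 specific links at the default study size)
run in minutes.

## Structure mapping and network compactness

PDB/mmCIF files are read through Biopython; one Cα per residue, altlocs
resolved to highest occupancy, missing residues simply absent (logged).
A numbering offset (`structure_number = site + offset`, default 0) is an
explicit user parameter because deposited constructs frequently differ
from search sequences. Distances are classified against a 40 Å
threshold — the ~30 Å DSBU maximum plus allowance for flexibility in
solution. Statistics use the population standard deviation and a
linearly interpolated 95th percentile (the two sd conventions differ by
well under 1% at realistic n).

The 3D embedding is a seeded Fruchterman–Reingold spring layout
(dim 3, 1000 iterations, default seed 27061971) where each edge's
attraction is the reciprocal of its target length; coordinates are
rescaled globally so the mean realized/target edge-length ratio is 1
(or, in compactness simulations, so the mean backbone neighbour
distance is exactly 3.8 Å — a single global scale factor). The
embedding is an abstract, topology-preserving layout, not an atomistic
model. Compactness simulations draw each cross-link length uniformly
from a range (default 26–30 Å), embed, rescale, and record the radius
of gyration, `Rg = sqrt(mean ||r_i − centroid||²)`; 20 simulations per
range by default.

## Synthetic ground truth

The generator emulates the measured study conditions: a 441-residue
chain with exactly 129 K/S/T/Y sites, 30 technical replicates of 75
observations per state (the typical per-replicate yield being 50–100),
and a second state created by re-growing residues 150–350. The
conformer is a fixed-bond (3.8 Å) random walk rejection-confined to a
30 Å sphere — chosen to give a chain of this length a compact,
protein-like radius of gyration (~18 Å) rather than free-coil
dimensions. Detection probability is `p_max = 0.9` up to the 30 Å
linker span and decays exponentially beyond with a 5 Å scale; 2% of
observations are replaced by uniformly random site pairs as
false-positive noise. Observations are drawn with replacement across
draws, so duplicates occur as in real data.

Re-growing a segment with both anchors present is a fixed-step random
*bridge*: each step is rejection-sampled under the feasibility bound
`|p − target| ≤ (remaining bonds)·3.8 Å`, with a deterministic
step-toward-target fallback, and the closing point is sampled exactly
on the two-sphere intersection circle. Confinement is honoured softly
during bridging; if a bridge point exits the sphere, the recorded
confinement radius of the returned conformer is widened accordingly.

What passing tests on this ground truth show: the pipeline recovers a
known contact-map rewiring from noisy, duplicated, replicate-structured
observations, end to end through the text formats. What they do not
show: robustness to search-engine scoring artefacts, to inter-molecular
contamination beyond the homeotypic filter, to heterogeneous
conformational ensembles (the generator has one conformer per state),
or to residue-composition biases in detectability.

## Problem sizes used in the shipped checks

The test suite runs the two-state recovery at the full default study
size (2,250 observations per state) across 10 seeds with a reduced
bootstrap depth for the largest-size comparison, and the full
six-point size grid at `n_boot = 10` for the threshold detection; the
acceptance script additionally runs the complete leave-one-out analysis
and the 20-simulation compactness estimate at 1,000 layout iterations.
These sizes are the package's reference configuration; all are
overridable parameters.
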