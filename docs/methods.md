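# Methods

## Content networks and the peptide-protein bridge

A sample's proteomic content network (PCN) is an S×F matrix over genera
and function identifiers. Functional annotation lives on protein groups
while taxonomy is resolved per peptide, so the two are joined through the
peptides: for each protein group, only member peptides that are *unique*
and whose lowest-common-ancestor (LCA) is at or below genus level count,
and the group's intensity is split across the supported genera
proportionally to each genus's summed unique-peptide intensity. The split
conserves the group's total intensity exactly; groups with no
genus-resolved unique peptide (or no annotation) contribute nothing.
Peptides whose LCA sits above genus level contribute neither to the
bridge nor to biomass: the analysis is deliberately genus-level, the
finest rank at which shared peptide sequences still allow confident
assignment.

Function identifiers merge two namespaces: KEGG KO when present,
otherwise COG. The namespaces cannot collide (K##### vs COG####). Rows
are normalized to sum to 1 **after** dropping unannotated groups, so each
row is the taxon's functional profile over annotated proteins. The
genomic content network (GCN) is built the same way from per-gene read
counts, without a bridge (gene tables already carry taxon labels).

Biomass proportions p_i are per-genus sums of unique-peptide intensities,
normalized within the sample. Intensities are assumed to be already
sample-normalized; the package never normalizes across samples, because
every quantity it computes is a within-sample quantity.

## Diversity, distance and redundancy

Functional distance between two taxa is the weighted Jaccard distance
between their row-normalized profiles; it is 0 for identical profiles and
1 for disjoint supports. Distances are always computed *within* the
sample under analysis: expressed proteomes respond to the environment, so
a pooled cross-sample reference profile would misstate every sample.

TD is the Gini-Simpson index without small-sample correction, FD is Rao's
quadratic entropy, FR = TD − FD, and nFR = FR/TD. Because d_ij ≤ 1, FD ≤
TD always holds and nFR lies in [0, 1]. For a single-taxon sample TD = 0
and nFR is defined as 0 — there is no pair of members to be redundant.
When a biomass profile and a network disagree on taxa (possible with real
search outputs), the shared taxa are kept and proportions renormalized.

## Topology

Networks are binarized at weight > 0 (no abundance cutoff — none is
justified a priori, and the weights are already relative). NODF follows
the classical overlap-and-decreasing-fill definition: a row pair
contributes overlap/fill(lower) only when the fills strictly decrease;
equal fills contribute 0; same over column pairs; the total is divided by
S(S−1)/2 + F(F−1)/2 and reported on the [0, 1] scale (the 0–100
convention divided by 100). The implementation is cross-checked in the
test suite against the independent NODF implementation in the R package
vegan (`nestednodf` with fill-ordered rows/columns).

## Null models

Because a function must be encoded before it can be expressed, PCN edges
are constrained to the GCN's edge set, and so are all null networks. PCN
edges absent from the GCN (annotation mismatches in real data) are
dropped with a logged count before randomization. The four variants:

* **null1** draws the PCN's edge count uniformly from GCN edges;
* **null2** draws, per taxon, a uniform subset of its GCN functions of
  its PCN degree;
* **null3** is symmetric per function;
* **null4** preserves both degree sequences by checkerboard trade moves
  — two edges (i,a), (j,b) are exchanged for (i,b), (j,a) only when both
  target cells are empty *and* GCN edges — run as a single chain with
  5×(edge count) successful trades as burn-in and again between samples.

Feasibility is guaranteed after background restriction (a taxon's PCN
degree cannot exceed its GCN degree); the check remains for direct API
use. Re-weighting after randomization is a genuine free choice: the
default gives each taxon's new edges equal weight 1/degree (fewest
assumptions), and a "permute" mode redistributes the taxon's original
weight multiset over its new edges (available when taxon degrees are
preserved, i.e. null2/null4). The permute mode is the cleaner instrument
for isolating the topology contribution to FR, since it holds per-taxon
weight heterogeneity fixed; the uniform mode also flattens weights, which
by itself can raise between-taxon similarity.

## Consumer-resource model with cross-feeding

Dynamics of M resources R_α and S taxa N_i:

    dR_α/dt = h_α − D R_α + Σ_i N_i (J_out,iα − J_in,iα)
    dN_i/dt = N_i [ Y (1−l) Σ_α J_in,iα − D ]

with J_in,iα = C_iα R_α and J_out,iβ = l Σ_α P_βα J_in,iα. The byproduct
matrix P is indexed with consumed resources as columns and byproducts as
rows; each column sums to 1, so leaked flux is conserved. A single
dilution rate D applies to both resources and microbes (fed-batch
assumption). Summing both equations at equilibrium gives the mass-balance
identity Σh = D(ΣR + ΣN/Y), which the test suite checks on random
multi-species systems.

Generators: per-taxon consumable-resource counts are Binomial(M,
connectance) (iid Bernoulli links) with U[0,1] rates; a taxon drawing
zero links receives one uniformly placed link so every pool member can in
principle grow. The sparse (PCN-level) matrix is an iid thinning of the
dense one with keep probability target/realized, so its support is a
subset and its rates identical. P has 50% connectance per column with
U[0,1] weights normalized per column.

Parameters not determined by the model statement were fixed once as
defaults and exposed as configuration: Y = 1, h_α = 1 h⁻¹ on round(ρM)
uniformly chosen resources, N_i(0) = 0.01, R_α(0) = h_α/D, t_end = 2000
h, extinction threshold 10⁻⁶. These let the default supply sustain
communities of meaningful richness at the default D = 0.2 h⁻¹, l = 0.5,
ρ = 0.2.

Integration uses LSODA (the system stiffens near extinction boundaries)
with rtol 10⁻⁸ / atol 10⁻¹⁰, states clipped at 0, in windows of 400 h
with early stop when the max relative state change per window falls
below 4×10⁻⁶ (10⁻⁸ per hour). The window length was chosen because
solver restarts dominate cost at short windows; final richness on probe
systems is unchanged between 10 h and 400 h windows and across rtol
10⁻⁵…10⁻⁸.

The paired experiment shares P, h, initial conditions and the dense
consumption matrix within each pair, thins to the sparse matrix, and
compares the two richness samples with a two-sided Mann-Whitney U test
(ties across all pairs ⇒ p defined as 1).

## Distance statistics

The "top 95% biomass" genus filter for distance distributions is applied
dataset-wide, on the mean biomass profile across samples, not per sample
— the retained genus set must be common for pairs to be comparable.
Genera tied at the cumulative boundary are all included. Pairs missing
from a sample (one genus absent) are recorded as missing, never as d = 1.

Jensen-Shannon divergence uses 50 equal-width bins on [0, 1] (exposed as
a flag), a 10⁻¹⁰ per-bin pseudo-count, and log base 2, giving values in
[0, 1]. Group-level JSD pools, by default, only genus pairs observed in
both groups, so it reflects shifted distances rather than differing pair
composition. Per-pair group comparisons use the two-sided Wilcoxon
rank-sum test on pairs observed in ≥ 2 samples per group, with
Benjamini-Hochberg correction across pairs; a pair with zero spread in
both groups gets p = 1.

## Synthetic data

The generator emulates the structure of real content networks — nested,
with fat-tailed degree distributions — not their biochemical content.
The PCN support starts as a prefix staircase from a geometrically
decaying row-degree sequence (decay 0.85), then a bisection-chosen number
of edges is moved to uniformly random empty cells; realized NODF is
measured on the nonempty submatrix (what network construction retains)
until it lands within 0.1 of the target. NODF = 1 is only constructible
as a square full staircase (equal fills contribute 0 by definition), so
perfect nestedness requires n_taxa = n_functions. The GCN is the PCN
plus uniformly placed extra edges up to the requested edge ratio, which
makes the expressed-within-encoded constraint true by construction.

Tables are then emitted per sample: one annotated protein group per PCN
edge, bridged by one genus-unique peptide whose intensity encodes both
the edge weight and the genus biomass (taxon totals proportional to a
lognormal biomass profile), plus non-unique and above-genus peptides that
must be ignored by a correct pipeline. Per-sample variation is
multiplicative lognormal noise (σ = 0.3) on weights and biomass; an
optional group effect multiplies a fixed fifth of the functions by
2^shift in the second half of the samples. Gene counts are Poisson draws
around lognormal means plus 1 on every GCN edge, keeping the support
exact.

What passing tests on these fixtures do **not** show: robustness to
search-engine artifacts (FDR filtering, razor peptides, missing values),
to cross-sample normalization issues, or to annotation coverage biases
in real KO/COG assignment — none of which the generator simulates.

Defaults (30 taxa, 120 functions, PCN connectance 0.12, PCN:GCN edge
ratio 0.25, 4 samples, NODF target 0.35) mirror the scale relationships
of real gut metaproteomes — sparse expressed networks at roughly a
quarter of the encoded edge count, moderate nestedness — at desk-test
size. Stand-ins for cultured single-strain proteomes are generated with
a shared core block, strain-specific blocks, and condition-specific
multiplicative perturbations; they are synthetic and labelled as such.

## Numerical conventions and edge cases

* Row normalization tolerance 10⁻⁹; FR = TD − FD maintained to 10⁻¹²
  (FD is clipped at TD against last-bit rounding).
* Weighted Jaccard uses Σmax = Σw_i + Σw_j − Σmin to avoid a second
  pass; distances clipped to [0, 1].
* Readers are strict: a missing column or malformed value raises with
  the column name or 1-based row number; rows are never silently
  dropped. Network TSV output orders rows lexicographically so files are
  byte-reproducible.
* All generators take integer seeds (or a shared `numpy` Generator) and
  are deterministic given them.

## Problem sizes in the test suite

Oracle-equivalence checks run 1000 random instances at S ≤ 6, F ≤ 10
against brute-force double-loop implementations. Null-sampler uniformity
uses 10,000 replicates on a 2×3 toy with an enumerable configuration
space. The paired assembly experiment in the test suite runs 25 pairs at
S = M = 100 (the acceptance script runs the full 100); with both medians
separated by ~50% of the smaller one, 25 pairs already decide the
rank-sum test at p < 10⁻⁸.
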