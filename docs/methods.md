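# Methods

## Model and procedure

The package operationalizes a network view of a two-condition phenotype
transition.  Genes that pass an expression filter and a differential-
expression screen form the nodes of an undirected graph; an edge joins two
genes when |Pearson ρ| of their profiles over all pooled samples strictly
exceeds a threshold, and the edge keeps the **signed** correlation as its
weight.  Signs matter: the Average Pearson Correlation Coefficient of a
node's neighborhood (APCC — the mean of its incident signed weights) can
only go negative when anti-correlated edges are preserved, and a negative
APCC is the defining mark of *fight-club* hubs.

Modules come from k-means under the correlation distance
dist(x, y) = 1 − ρ(x, y) ∈ [0, 2].  Each node then receives two role
coordinates:

* **K_π = 1 − (k_in/k)²** (clusterphobic coefficient): 0 when all links are
  internal to the node's module, → 1 when most links leave it.  Link counts
  ignore weight signs.
* **z_g = (k_in − k̄_C)/σ_C** (within-module degree): the z-score of the
  node's internal degree against its module's internal-degree distribution.

The (K_π, z_g) plane is carved into seven roles.  Non-local hubs
(z_g < 2.5): R1 (K_π ≤ 0.05), R2 (≤ 0.625), R3 (≤ 0.8), R4 (> 0.8); local
hubs (z_g ≥ 2.5): R5 (K_π ≤ 0.30), R6 (≤ 0.75), R7 (> 0.75).  These
boundary constants follow the standard role cartography for complex
networks; all are configurable (`RegionBounds`).  Hubs are nodes of degree
strictly exceeding 5; they split by APCC into fight-club (< 0), date
(0 ≤ APCC < 0.5) and party (≥ 0.5) hubs.  The date/party split at 0.5 is a
convention (the literature says only "low" vs "high") and is configurable.

**Switch genes** are the fight-club hubs in R4: z_g < 2.5, K_π > 0.8,
APCC < 0, degree > 5.  The hub requirement makes the switch set a subset of
the fight-club set by construction.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `max_zero_samples` | S/2 | max zero entries a gene may have (S = samples) |
| `iqr_percentile` | 25 | genes below this percentile of the IQR distribution are dropped |
| `fc_threshold` | 1.5 | cutoff on the absolute log₂ fold-change |
| `fdr_threshold` | 0.05 | BH-adjusted t-test cutoff |
| `rho_threshold` | 0.71 | correlation cutoff for edges (strict inequality) |
| `k` | 3 | k-means module count (scree output guides the choice) |
| `replicates` | 100 | random k-means restarts; lowest SSE wins |
| `hub_degree_threshold` | 5 | hub = degree strictly above this |
| `apcc_split` | 0.5 | date vs party boundary |

Fold-change conventions: on log₂-scale input the log-FC is the difference
of condition means; on linear input it is log₂ of the ratio of means (the
scale is declared explicitly — no auto-detection).  The FC cutoff is
interpreted on the log₂ scale.  The t-test is the classic pooled-variance
Student's t (Welch behind a flag); genes with zero variance in both groups
get p = 1 when the means agree and p = 0 otherwise.  BH runs over all
tested genes before thresholding.

## k-means under correlation distance

Lloyd iteration with coordinate-wise-mean centroids, assignment by maximum
Pearson correlation to the centroid, and SSE = Σ dist² as the objective.
Initial centroids are k distinct profiles drawn over the canonical
sorted-node order, which makes results independent of input row order;
every replicate draws from an independently spawned substream of the seed.
Two numerical choices deserve note:

* The coordinate-mean centroid is not the exact minimizer of Σ(1 − ρ)², so
  a Lloyd step is not guaranteed to lower the SSE.  An iteration that would
  raise it stops the replicate at the previous state; the recorded SSE
  trajectory is therefore nonincreasing.  In practice this guard almost
  never triggers on separated data.
* An emptied cluster is repaired by donating the point farthest from its
  current centroid (one repair pass per iteration).

Convergence is declared when assignments stop changing.  The scree helper
runs each k on its own derived stream, so extending the k range never
changes results at other ks.  Elbow picking is deliberately left to the
user.

## Null model and robustness

The degree-preserving null performs `swap_factor · |E|` attempted double
edge swaps; a swap requires four distinct endpoints and must not create an
existing edge, so the graph stays simple and every degree is preserved
(asserted on each call).  Edge weights travel with the first-named endpoint
of each swapped edge.  Graphs with no legal swap (stars, triangles) are
returned unchanged with a warning flag.

The average shortest path is the mean unweighted BFS distance over
reachable node pairs; pairs in different components are excluded from the
mean (a documented convention — the harmonic-mean alternative was not
adopted), and an edgeless graph has no defined value.  Robustness curves
delete nodes of one class one at a time in decreasing degree order, with
degrees frozen on the intact network and ties broken by node id; the
`random` class averages 50 independently seeded uniform-deletion runs.

Caveat: targeted deletion dominates random deletion only on networks whose
global connectivity actually runs through the targeted class.  On the
default synthetic preset the planted regulators attach to a single module,
so they are topologically redundant and the dominance contrast is tested on
`generate_switch_network`, a fixture whose modules are bridged exclusively
by anti-correlated connector hubs.

## Enrichment and survival

Over-representation uses the upper-tail hypergeometric probability
p = P[X ≥ x] with, by default, an interaction-counting universe: M is the
total number of (gene, set) membership pairs in the collection, K the
selected set's size, N the query genes recognized by (in at least one set
of) the collection, X the query genes in the selected set.  This mirrors
the published convention for miRNA-target enrichment but is **not**
calibrated for random gene queries (M is inflated by multi-set membership;
measured ~0.11 of random-query p-values fall below 0.05).  The
conventional gene-counting universe (`universe="genes"`), which is
calibrated, is available and used for the calibration checks.  Rows are
ranked by raw p; BH values are appended.

The survival screen splits patients at the 50th percentile of each gene's
expression (values exactly at the percentile join the low group), compares
the groups with the standard 1-df log-rank test (no continuity correction)
on Kaplan–Meier product-limit estimates with right censoring, and adjusts
over the gene list with BH; genes whose expression cannot be split report
p = NA and are excluded from the BH denominator.

## Synthetic data

`generate_expression` uses a latent-factor model on the log₂ scale: module
gene = baseline + condition shift + noise_sd · (a·f + √(1−a²)·ε) with
a = √ρ_intra, so the expected within-module correlation is ρ_intra; the
20 regulators load negatively on module 1's factor
(c = ρ_reg/√ρ_intra < 0, expected regulator–module correlation ρ_reg) and
carry −de_log_fc while module genes carry +de_log_fc (split symmetrically
across the conditions).  Filler genes are i.i.d. noise.  Defaults: 1000
genes, 3×100-gene modules, 20 regulators, ρ_intra = 0.8, ρ_reg = −0.7,
de_log_fc = 2, noise_sd = 1, baseline ~ U(4, 8) log₂ units, 15+15 samples.

Factor realizations are centered, mutually orthogonalized and variance-
normalized within each condition block.  This enforces the generator's
contract at the realized-sample level: the planted fold-change is exactly
de_log_fc in expectation per gene (factor sampling noise cannot shift a
whole module's group mean), and chance correlation between factor draws
cannot create spurious dense cross-module edge blocks.  Two consequences
worth knowing: pooled-sample correlations exceed the within-condition
targets whenever shifts are planted (deliberately — the shift is what makes
regulators strongly anti-correlated with module 1 in the pooled network),
so the ±0.05 correlation check is run with de_log_fc = 0; and between-
module correlations still sit near 0.5 from the shared shift, below the
0.71 edge threshold.

All randomness flows from one seed through named substreams (expression /
genesets / clinical), so adding one generator never perturbs another.
`generate_genesets` plants one target set overlapping the regulators at a
configured rate among random sets; `generate_clinical` draws exponential
survival with hazard log-linear in a chosen gene's standardized expression
plus independent exponential censoring.

What the generator does *not* emulate: microarray probe effects, batch
structure, heavy-tailed FPKM distributions, overlapping modules, or hub
degree heterogeneity within modules.  Passing tests demonstrate that the
pipeline recovers the planted structure under clean factor-model
assumptions; they do not certify behavior on real platform noise.

## Mode counting

The trimodality check on the hub APCC distribution is a kernel-free
bin-count rule: histogram on [−1, 1] with bin width 0.1; a mode is a
maximal run of adjacent bins each holding at least max(2, 2% of the sample)
values, and separated runs are separate modes (the floor keeps sparsely
populated bridge bins from fusing two peaks).  Reported mode positions are
count-weighted run centers.

## Degenerate inputs and conventions

* z_g in a module with zero degree spread is defined as 0.
* Isolated nodes stay in the node set but are flagged `isolated` and are
  excluded from APCC, hub classification and switch calling.
* The module statistics behind z_g use members' internal degrees and the
  population (n-denominator) standard deviation; both choices are
  configurable (total degrees / sample sd) because the defining texts are
  ambiguous on this point.
* The IQR filter is relative to the current gene set, so it is not
  idempotent: re-applying it trims the new bottom of the IQR distribution
  again.  Only the absolute zero-count stage is idempotent.
* Strict inequalities: edges need |ρ| > threshold; hubs need degree >
  threshold; switch genes need K_π > 0.8 and APCC < 0.

## Problem sizes

Validation runs use the default preset (1000 genes, 30 samples; ~320-node
networks with ~17k edges), ten simulation seeds for recovery statistics,
5–10 null-model draws, 50 random-removal repeats, 20 replicate null
matrices for FDR calibration and 500 replicates for log-rank type-I error —
sizes at which every check completes in seconds to a couple of minutes on a
single CPU while keeping Monte-Carlo error well below the asserted margins.

## Known limitations

* k-means with correlation distance inherits k-means' local-minimum
  behavior; the replicate scheme mitigates but does not eliminate it.
* The interaction-counting enrichment universe follows the published
  convention even though it mixes genes and interactions; switching
  universes changes p-values materially (see above).
* The pipeline assumes complete (NaN-free), already-normalized expression
  matrices; probe summarization and normalization are out of scope.
* Pooled-sample correlation conflates within-condition co-regulation with
  between-condition mean shifts; that conflation is intrinsic to the
  method (it is what surfaces condition-linked anti-correlation) but means
  edge weights are not estimates of within-condition co-expression.
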