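# Methods

## The screening model

The screen tests, per gene, whether the mean log2 intensity differs between
the experimental and control groups. With only a handful of replicates the
per-gene variance estimate is the bottleneck, so the random variance model
is used: the per-gene precision σ⁻² is assumed exchangeable across genes
with a Gamma(a, b) prior (shape a, scale b; prior mean precision a·b).
Marginally the residual variance s² on m degrees of freedom then satisfies

    s² · a · b ~ F(m, 2a),

and (a, b) are estimated once, across all genes, by maximizing the
corresponding likelihood (L-BFGS-B on (log a, log b), gradient tolerance
1e-8, a bounded in [1e-3, 1e4]). The moderated variance

    s̃² = (m s² + 2/b) / (m + 2a)

replaces the pooled variance in the two-sample t statistic, which is
referred to a t distribution on m + 2a degrees of freedom. Two limits
anchor the implementation: a → 0 with 1/b → 0 recovers the classical
pooled t-test (the flat-prior limit, asserted against an independent
implementation in the tests), and large fitted a approaches a z-test with
the genome-wide variance — which is also what happens, correctly, when the
data are homoskedastic across genes. Degenerate inputs (fewer than 50
positive variances, or all variances identical, under which the likelihood
is unbounded) reject the fit and the code falls back to the ordinary
pooled t-test with an explicit warning.

Testing runs on log2 intensities; fold changes are ratios of raw-scale
geometric means (equivalently 2^(difference of mean log2 values)), with
trend "up" for ratio > 1, "down" for ratio < 1 and an internal "flat"
label for exact ties, which cannot survive the significance filter. The
two conventions together are the only pair consistent with report tables
that print per-group geometric-mean intensities next to the fold change.
Multiplicity is handled by Benjamini–Hochberg throughout; selection is
strict (p < 0.05 AND FDR < 0.05). Zero moderated variance (possible only
in noise-free synthetic data) maps to p = 0 for a nonzero mean difference
and p = 1 otherwise, so exact recovery remains well defined.

## Enrichment

For a term with n annotated genes of which n_f are differential, against a
universe of N genes with N_f differential, significance is the one-sided
hypergeometric tail P(X ≥ n_f) (Fisher exact, over-representation only)
and the effect size is the enrichment ratio Rₑ = (n_f/n)/(N_f/N). The χ²
statistic (1 df, no continuity correction) is reported alongside but is
flagged invalid whenever an expected cell is below 5 and never governs
selection. The universe in each category is the set of genes carrying at
least one annotation there — genes with no annotation cannot enter any
2×2 table. Up- and down-regulated lists are screened separately plus a
combined pass; FDR families are category × direction. A term's color in
the term networks is "up"/"down" when significant in exactly one
directional pass and "both" otherwise.

## Networks

All networks share one container and three statistics:

* **degree** counts distinct neighbors (a reciprocal directed pair is one
  neighbor but contributes to both indegree and outdegree) — the only
  convention under which a hub row like degree 17 / indegree 16 /
  outdegree 16 is self-consistent;
* **betweenness** is Brandes shortest-path betweenness normalized by
  (N−1)(N−2) (directed) or (N−1)(N−2)/2 (undirected), so values live in
  [0, 1]; graphs with fewer than three nodes are all-zero;
* **k-core** is the iterative-pruning core index on the undirected simple
  projection.

The GO map links each significant term to its nearest significant
ancestors: an edge u → v is drawn when some hierarchy path from u to v
contains no other significant term. Sub-networks are weakly connected
components of size ≥ 2 by default (the threshold is exposed — published
component counts depend on an unstated minimum size). The pathway network
keeps curated pathway–pathway adjacencies whose endpoints are both
significant and ranks pathways by degree; when no curated adjacency file
exists, a helper derives one from shared-gene counts (≥ 1 by default).
The signal network induces a curated signed, directed gene–gene edge list
on the differential genes (edges with a non-differential endpoint are
dropped and counted) and ranks genes by betweenness, then degree, then id.

Co-expression networks are built per group on log2 intensities: an
undirected signed edge requires |R| ≥ 0.8 AND a two-sided correlation test
p < 0.05 on n − 2 df. Both gates are parameters because with three samples
per group the p gate alone is effectively |R| > 0.997 — the magnitude gate
is what carries small designs, and the dual-gate default is declared, not
inferred from any publication. Profiles that are constant within a group
(including numerically constant ones — float jitter from exp/log round
trips is masked by a relative tolerance of 1e-8) stay isolated. The gene
subset defaults to the differential members of significant GO terms, with
a flag to use all differential genes. Cross-group comparison reports
degree, core index and signed partner sets per gene; `status_change` flags
any difference.

## Hub nomination

The narrative decision "combined the results of the pathway network and
the gene co-expression network" is formalized as an explicit evidence
count over three streams: (a) membership in ≥ 1 significant pathway,
(b) betweenness within the top K = 10 of the signal-network ranking (zero
betweenness never counts), (c) co-expression k-core ≥ 5 in either group or
a status change between groups. A gene is called with ≥ 2 streams. All
three thresholds are configuration fields; raising `min_evidence` can only
shrink the called set (asserted as a property test). RT-PCR concordance is
reported alongside the hub report but does not gate it.

## qPCR

The Livak 2^−ΔΔCt form: per sample ΔCt = Ct(gene) − Ct(reference), ΔΔCt is
the difference of group-mean ΔCt values, ratio = 2^−ΔΔCt. Arithmetic
averaging of replicate ΔCt equals geometric averaging of per-replicate
ratios. The reference gene defaults to β-actin (Actb) and is a parameter,
because study write-ups sometimes name conflicting internal controls. No
amplification-efficiency correction is applied. Concordance with the
intensity screen is same-side-of-1 trend agreement.

## The synthetic generator

The generator emulates the study conditions the package was built around:

| parameter | default | rationale |
| --- | --- | --- |
| n_genes | 2000 | desk-scale stand-in for a ~20k-gene array |
| n_samples_per_group | 3 | the motivating 3 vs 3 design |
| de_fraction | 0.1 | ~6% of array genes were differential; 0.1 keeps planted sets usable at 2000 genes |
| fold_change_range | 2–47.26 | the span reported for strongly responding genes |
| up_fraction | 0.4 | ≈ 460 up / 1175 total in the motivating screen |
| noise_sd_log2 | 0.25 | typical replicate SD of RMA-normalized biological replicates |
| baseline_log2_mean/sd | 8 / 1.5 | intensity scale of the printed per-group geometric means |
| enrichment_odds | 15 | planted over-representation strong enough to be unambiguous against the annotation-restricted universe |
| term_size_range | 15–40 | small enough to be realistic, large enough that a planted term cannot vanish by sampling noise |
| hub_spec | 3 hubs (16/10/8 spokes, ρ 0.90–0.95) | hub dominance at the scale of published hub tables |

Intensities are 2^(Gaussian): log2 values are baseline + group shift +
latent-block component + iid noise, which makes geometric-mean ratios the
exact planted folds. Differential genes shift the experimental-group mean
by ±log2(fold), with log-uniform fold magnitudes. Hub correlation blocks
share a per-sample latent factor with loading σ·√(ρ/(1−ρ)), giving
expected within-group pairwise correlation ρ; at zero noise the loading is
zero too, so the noise-free matrix is an exact rendition of the planted
means (and, deliberately, carries no co-expression signal). Interaction
edges give each hub its block members as incoming spokes and all but one
of them plus one fresh gene as outgoing spokes — reproducing the
degree = n+1, indegree = outdegree = n hub pattern — with background edges
at `random_edge_rate` per differential gene. Because blocks are disjoint
and spokes touch only their own hub, a zero-background configuration makes
the planted hubs the only positive-betweenness nodes, which is what makes
noise-free end-to-end recovery exact rather than probabilistic. All
randomness flows from one seed through per-artifact generator streams;
re-runs are bit-identical.

What the generator does *not* emulate: probe-level effects and RMA
internals, batch effects, heteroskedastic per-gene noise, correlated
background structure beyond the planted blocks, and annotation bias. Tests
passing on this generator therefore demonstrate correctness of the
statistics and the recovery machinery under the declared model, not
performance on real arrays.

## Problem sizes used in the checks

The bundled checks run a 10,000-gene null simulation for type-I
calibration (the fraction of p < 0.05 must sit in [0.04, 0.06]), the
2000-gene default-noise condition for recovery (DE sensitivity ≥ 0.8,
realized false discovery ≤ 0.1, enriched-term sensitivity ≥ 0.9, planted
hub first by betweenness), and an 800-gene noise-free condition for exact
end-to-end recovery. Brute-force oracles cap at 12 nodes (betweenness), 30
nodes (k-core) and N ≤ 30 (Fisher enumeration), where exhaustive
enumeration is cheap and exact.

## Known limitations

* The RVM fit assumes variances exchangeable across genes; strong
  mean–variance trends (common in count data) are not modeled.
* The published PathNet statistic (combining direct and indirect pathway
  evidence) is not implemented; the pathway network is built from an
  explicit adjacency input, which reproduces the published use of the
  network (degree-ranked significant pathways) without the inferential
  machinery.
* GO annotations are treated as pre-propagated; no OBO parsing or
  ancestor propagation is performed.
* With n = 3 per group, co-expression edges are near-anecdotal whatever
  the thresholds; the per-group networks are reported faithfully but hub
  calls in small designs rest mainly on the pathway and betweenness
  streams.
* No claim is made of recovering any specific published hub-gene list:
  that would require the original arrays, which are not deposited.
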