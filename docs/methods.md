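# Methods

This note documents the models and procedures implemented in
`netproxrx`, the assumptions behind them, the parameters that matter,
and the design choices made where the methodology was genuinely open.

## Interactome model

The interactome is an undirected, unweighted simple graph of gene
identifiers. Self-loops are dropped and duplicate or reversed edges
collapse on construction. Distances are hop counts: real assembled
interactomes are unions of heterogeneous binary interaction evidence,
so edge weights would be artifacts of source coverage rather than
biology.

All proximity computation is restricted to the largest connected
component (LCC). Assembled human interactomes are dominated by one
giant component, and the restriction guarantees every pairwise distance
is finite. Disease genes and drug targets outside the LCC are dropped
with a logged report; a drug whose whole target set falls outside is
excluded from scoring (and counted), since its proximity is undefined.

For graphs up to 6,000 nodes an all-pairs distance matrix is computed
once with `scipy.sparse.csgraph` (BFS per source, float32) and cached
on the instance; set-to-set distance queries — of which a permutation
run makes hundreds of thousands — then reduce to a submatrix min/mean.
Larger graphs use one multi-source BFS per query. The two backends are
exact and interchangeable (asserted by test), differing only in cost.

## Proximity and its null

The proximity of drug targets *T* to disease genes *D* is the
closest-distance average `d(T,D) = mean_t min_g sp(t,g)`, the standard
interactome drug–disease proximity. It is 0 exactly when every
in-graph target is itself a disease gene.

Significance is assessed against a degree-preserving null: nodes are
sorted by degree and grouped into contiguous bins of at least
`min_bin_size` nodes (default 100; degree classes are never split, and
an undersized final remainder merges into the previous bin). Each
permutation replaces **both** *T* and *D* with sets drawn
degree-matched from those bins, without replacement within a draw, so
null sets preserve the cardinality and hub/leaf profile of the observed
sets. Degree matching is essential because hubs are close to
everything; an unmatched null would flag every hub-targeting drug as
proximal. The default is `n_perm = 1000`; per-drug permutation seeds
derive from SHA-256 of the master seed and the drug id, so batch
results are independent of drug ordering and reruns are byte-identical.

The z-score uses the sample standard deviation of the null distances
(degenerating to 0, with a warning, if the null has no spread). The
empirical p-value is

    p = (#{d_rand < d_obs} + 0.5 * #{d_rand = d_obs} + 1) / (n_perm + 1)

Ties are counted at half weight. Hop-count proximities live on a grid
of 1/|T|, and at drug-like target counts ties between observed and null
distances carry 10–20% of the mass; counting them fully makes the
p-value visibly conservative (it fails a Kolmogorov–Smirnov uniformity
check under a true null), while the mid-p convention restores
uniformity. The +1 pseudocount keeps p ≥ 1/(n_perm+1) > 0.

Similarity is a batch min–max rescale of distances: the most proximal
drug(s) in a scored batch get exactly 1, the most distant 0, ties share
a value, and if all distances coincide everyone gets 1. The transform
is recomputed from distances on every call, so it is idempotent and
order-invariant. It is a *relative* score: values are comparable within
one scored batch only.

An optional cluster adjustment (off by default) multiplies each
similarity by a logistic gate `σ(s) = 1/(1+exp(-k(s-m)))` (defaults
k = 30, m = 0.5) for same-cluster drug–disease pairs and by `1-σ(s)`
for cross-cluster pairs, with clusters from Louvain community detection
over the weighted bipartite drug–disease similarity graph. This stage
is a reconstruction of similarity-network post-processing used by some
pipelines; it is provided for completeness and clearly separated from
the core statistic.

## Differential expression and signature reversal

The expression arm consumes precomputed per-dataset differential
statistics (gene, signed effect, raw p) — fitting the expression models
themselves is out of scope. Raw p-values are Benjamini–Hochberg
adjusted per dataset independently (via `statsmodels`), and genes with
adjusted p strictly below alpha (default 0.05) are split by effect sign
into the dataset's up/down signature. Zero-effect survivors cannot be
assigned a direction and are dropped with a log message; an empty
signature is returned flagged rather than raised, and skipped in
downstream counting.

Drug profiles are ranked gene lists with aligned non-increasing scores.
Enrichment of a gene set in a profile is the classic weighted-KS
running sum (weight exponent 1): walking the ranking, the sum rises by
`|score|/Σ|score|` at set members and falls by `1/(L-k)` otherwise; the
statistic is the signed extremum, in [−1, 1]. The implementation
matches gseapy's reference routine exactly on shared inputs. Note that
with weight 1 a random gene set fluctuates more than under the
unweighted KS (median |ES| ≈ 0.26 for a random 50-of-1000 set with
normal scores), because weight concentrates where |score| is large.
Degenerate inputs: a set covering the whole ranking returns 1; all-zero
member scores fall back to equal weights.

The connectivity score follows the two-sided WTCS convention:
`(ES_up − ES_down)/2` when the two enrichments have opposite signs, 0
otherwise. No tau-normalization against a reference compendium is
applied — only the sign of the score is consumed downstream, and the
sign is invariant to monotone rescaling. If a disease signature has
only one direction the score falls back to the single available
enrichment (sign-flipped for the down set). Multi-profile drugs
(several cell lines) are collapsed per dataset by keeping the value of
largest magnitude (ties break toward the negative); a majority (median)
mode is available.

A drug's integer GSEA score counts the datasets with strictly negative
connectivity — zero does not count as reversal. The score is NA only
when the drug has no profile in the library at all; a drug–dataset pair
whose signature does not overlap the profile simply contributes
nothing.

## Prioritization

Drugs are kept when their empirical p is strictly below alpha (default
0.05), then sorted by similarity descending, GSEA score descending,
and drug name ascending case-insensitively (drug id as final
tie-break). NA GSEA sorts below 0 within a similarity tie: no reversal
evidence ranks below evidence of zero reversal. Ranks are consecutive
from 1. The radial export maps each candidate to radius 1 − similarity
(most proximal at the center) with the GSEA score as color key, and can
be filtered to one target-annotation class.

## Synthetic data: what it emulates and what it does not

The generator produces every pipeline input with planted truth.

* **Interactome**: a Barabási–Albert preferential-attachment graph
  (default 2,000 nodes, 3 edges per new node). This reproduces the
  heavy-tailed degree distribution of real PPI networks — the property
  the degree-matched null exists to control — but none of their local
  structure (clustering, complexes, pathway modularity).
* **Disease module**: a connected subgraph grown by random frontier
  expansion (default 25 genes), emulating the disease-module hypothesis
  that disease genes cluster in a network neighborhood.
* **Drugs**: proximal drugs (default 10) draw their targets (default 3)
  from the module and its first neighborhood; random drugs (default 40)
  draw a proximal-style template and replace it with a degree-matched
  sample from anywhere, so the two classes share a degree profile and
  separation cannot come from target degree alone.
* **Signatures**: three datasets of 200 measured genes each; 40 up and
  40 down genes per dataset are planted with raw p in [1e-8, 1e-5]
  (background in [0.2, 1]), so the planted split survives BH at 0.05
  cleanly at zero noise. Datasets draw their signature genes from
  shared up/down pools, emulating a common disease program across
  cohorts, so one drug profile can reverse all datasets at once.
  Reversing drugs place each disease-up gene at the bottom of their
  ranking (strongly negative score) with probability
  `reversal_strength` (default 0.8) and vice versa; `noise_p` (default
  0.05) flips individual placements; null drugs are standard-normal
  background; "absent" drugs are left out of the library to exercise
  the NA path. Expression values have no correlation structure, batch
  effects, or realistic effect-size distributions.

Ground-truth labels live in a sidecar TSV the pipeline readers never
consume. Passing tests on these data show the statistics recover the
signal they were designed for under their own assumptions; they do not
show robustness to the ways real interactomes and transcriptomes
violate those assumptions (ascertainment bias, literature coverage,
correlated expression noise).

## Problem sizes and numerical choices

The pipeline-level test battery uses desk-scale problems chosen to make
the assertions statistically meaningful at interactive runtimes: the
proximity oracle check runs 200 random graphs of up to 50 nodes against
brute-force all-pairs shortest paths; null calibration uses 500
replicates of 5-target/20-gene sets on a 1,000-node graph at
n_perm = 200 (KS uniformity at α = 0.01); planted-signal recovery runs
the default 2,000-node configuration over 5 seeds at n_perm = 200 and
requires median AUC ≥ 0.9; signature recovery uses 150 random drugs so
that at least 50 are null. The full suite completes in about half a
minute on one CPU.

Other numerical conventions: tied proximities get identical similarity
(ties are biologically meaningful — shared targets); drug profiles with
tied scores are ordered deterministically by gene id; LCC ties break
toward the component containing the lexicographically smallest node;
all randomness flows from explicit integer seeds through
`numpy.random.default_rng`.

## Known limitations

* Similarity is batch-relative; adding or removing drugs rescales it.
* The closest-distance kernel is the only proximity measure provided
  (the literature also uses shortest, centre, and separation kernels).
* The cluster adjustment is a labeled reconstruction, not a validated
  reimplementation of any specific published pipeline stage.
* GMT-pair drug signatures carry sign structure only (+1/−1 scores), so
  their connectivity scores are coarser than ranked-profile input.
* The empirical p resolution is bounded by 1/(n_perm+1); significance
  filtering at alpha = 0.05 needs n_perm ≥ 20 to be able to reject at
  all, and n_perm = 1000 for stable selection near the threshold.
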