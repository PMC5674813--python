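# Methods

This note documents the models, estimators and numerical choices behind
`olnet`, what the synthetic-data generator does and does not emulate, and
the design decisions taken where more than one reasonable option existed.

## Synthetic data model

The generator plants exactly the structure the downstream stages assume,
so that every stage has a recoverable ground truth.

**Regulatory network.** Genes are laid out in a fixed topological order
and partitioned into contiguous module blocks, so intra-module edges
always point forward and the graph is acyclic by construction. Each
module's first gene is its designated hub and receives direct out-edges to
at least 30% of its module — a plantable key driver whose downstream reach
dominates the module. Remaining edges are drawn per gene (Poisson, mean
`edges_per_gene`) preferentially within the module (default 85%). Edge
effects are signed with magnitudes uniform on [0.5, 1.5]. True in-degree
is capped at 3: genes have few direct transcriptional regulators, and the
cap matches the structure-search bound so that recovery benchmarks are
well-posed. A configurable fraction of genes (default 30%) receives a
cis-eSNP anchor.

**Expression.** Root genes (no regulators) draw N(0, 1); regulated genes
are the effect-weighted sum of their parents plus N(0, `noise_sd`)
residual noise. This unit-variance-root convention makes the
signal-to-noise ratio of an edge interpretable: a chain A→B with effect 1
and noise 0.1 gives cor(A, B) ≈ 0.995. eSNP-anchored genes add
`esnp_effect` × dosage, with dosages Binomial(2, allele frequency)
(Hardy–Weinberg, default frequency 0.3 — the magnitude of real cis
effects is cohort-specific, so this is a tunable, not a claim). Defaults
(three regions, 100 samples/region, 200 genes) are a desk-scale stand-in
for a multi-region postmortem cohort.

**Knockout counts.** Ablating a driver sets its mean to exactly 0 in KO
samples. Effects propagate down directed paths: the driver carries a log₂
effect of −2 and each edge transmits `attenuation` (default 0.5) times the
parent effect, signed by the edge's regulatory sign — so effects decay
layer by layer, which is what makes layerwise enrichment informative.
Continuous means become negative-binomial counts (gamma–Poisson,
dispersion 0.1) at library sizes jittered 10% around 200k. Both
conditions are normalized by the WT mean total, so genes not downstream of
the driver keep the same expected rate: the generator deliberately omits
the compositional bias real library-size normalization can induce, keeping
non-descendant genes exactly null (verified by a KS-uniformity test).

**Proteomics contrast.** Module features are equicorrelated Gaussian with
pairwise correlation `r_control` in the Braak 0–2 group and `r_case` in
the Braak 5–6 group (defaults 0.6 vs 0.2); background features are
independent. Positive-definiteness (1 + (m−1)r > 0) is enforced.

**What passing tests do not show.** The generator is linear-Gaussian with
NB counts; it has no batch structure, no heavy-tailed or skewed marginals,
no missingness beyond what tests inject, no probe-level duplication, and
no cross-species homology complications (harmonization is exercised only
via case-insensitive symbol matching). Recovery results on this data
certify internal correctness of the estimators, not performance on real
cohorts.

## Coexpression

Unsigned adjacency |r|^β throughout (the absolute value makes repressive
and activating relationships equivalent). β defaults to the scale-free
criterion — smallest candidate power whose signed fit R² reaches 0.8,
argmax fit otherwise — while proteomics-style analyses conventionally use
β = 3. The scale-free fit regresses log₁₀ bin frequency on log₁₀ mean
connectivity over 10 linear bins; constant connectivity raises an explicit
"fit undefined" error rather than returning a number.

Module detection is average-linkage hierarchical clustering on 1 − TOM
with a **static** branch cut (default height 0.995) and reassignment of
clusters below the size floor to "unassigned". This deviates from the
dynamic hybrid tree cut many workflows use: the static cut is fully
specified, deterministic, and sufficient to recover planted modules;
module labels are drawn from a fixed color list in descending size order
(size ties broken by smallest member id) so runs are reproducible.
Missing values use pairwise-complete correlation with a 10-observation
floor; pairs below the floor, and pairs involving zero-variance features,
become zero adjacency and are excluded from module statistics. Covariate
correction (batch/age/sex for proteomics) is per-feature least-squares
residualization with dummy-coded categoricals.

## Enrichment

All tests are one-sided (over-enrichment) Fisher exact tests: the analyses
this package supports report enrichments, and FE > 1 claims pair naturally
with an upper-tail p. The universe is explicit in every call — all
measured features for expression enrichments, all network genes for
neighborhood validation — and every result records the universe used. BH
adjustment scope differs by analysis and is fixed per function: across the
whole module × cell-type matrix for annotation; within each DEG set for
GO-style enrichment; across the layer set for driver validation. The GO
term-size window is strict on both ends (100 < size < 800, after universe
intersection).

The m-way intersection test treats each set as a uniform draw of its size
without replacement. The running intersection is a Markov chain — given
current size s, the overlap with the next set of size n is
Hypergeometric(N, s, n) — and convolving the kernels yields the exact
distribution of the m-way intersection size. All arithmetic is in log
space (log-gamma binomials + logsumexp), so tail probabilities of order
1e-80 and smaller are computed without underflow. FE is observed /
expected with expected = N·Π(nᵢ/N).

## Causal networks

Structure learning is score-based: linear-Gaussian BIC,
score(v|P) = −(n/2)·log σ̂²(v|P) − ((|P|+1)/2)·log n, with residual
variances computed from the standardized sample covariance by Schur
complement (numerically stable, cache-friendly, and likelihood-equivalent,
so Markov-equivalent DAGs tie exactly up to floating point — with the
prior weight at 0, the two orientations of a dependent pair score
identically to ~1e-14 relative).

The cis-eSNP prior is an additive orientation penalty, not a hard
constraint: an edge s→t with more eSNPs on t than on s loses ln 10 of
score. Anchored genes therefore resolve as sources within an equivalence
class but can still be overridden by strong conditional-independence
evidence. Genotypes enter only through these counts; dosages are not
network nodes.

Search is greedy hill climbing over add/delete/reverse moves (max
in-degree 3, strict score improvement, first-found tie-break in
lexicographic (source, target) order) wrapped in iterated local search:
after the initial climb from the empty graph, each round perturbs the
incumbent (a quarter of its edges deleted or validly reversed) and
re-climbs, with every fourth round a random sparse restart for
diversification; the best-scoring structure wins. The default budget of
200 rounds was set by score auditing — comparing the search optimum with
the planted structure's score — which showed small budgets (≈10 rounds)
leaving score gaps of hundreds of log units on 20-node problems, while at
200 rounds the gaps are ≈0 and mean directed-edge F1 reaches ~0.79 at
n=500. The orchestrated pipeline uses a smaller budget (4 rounds) for its
larger module networks, trading recovery sharpness for runtime; both are
plain config knobs.

Orientation accuracy is reported on the prior-informative subset: true
edges whose source is anchored and target is not. Anchored→anchored pairs
carry equal counts, so the prior cannot orient them and they are excluded
from that metric (they still count in edge F1).

The union of region networks concatenates directed links, deduplicating
only exact (source, target, region) triples. It is deliberately not forced
acyclic: regions that disagree on orientation produce reciprocal edge
pairs, which downstream traversal handles with a visited set.

## Key drivers and validation

The driver score is plain downstream reach — the size of the n-layer
(default 5) directed neighborhood, excluding the gene itself, with
parallel provenance edges counted once. The key-driver call requires both
rank ≤ top-N (default 40) and score > mean + 1 SD of all node scores; the
literature offers several KDA variants, and this simple reach statistic is
the one whose behavior the planted-hub generator directly tests. Ranks
tie-break by out-degree then identifier. On small dense unions the reach
of many genes saturates and the mean + 1 SD gate becomes conservative;
this is visible in the examples and is a property of the gate, not a bug.

Validation tests, for each depth n = 1..5, the Fisher enrichment of a
perturbation DEG signature in the driver's n-layer neighborhood, with BH
adjustment across layers. Signatures are restricted to the declared
universe first; empty signatures raise rather than silently returning
nulls.

## Differential statistics

**MDC** is the mean over module gene pairs of z_case − z_control with
z = arctanh(r) (Fisher's variance-stabilizing transform; |r| clipped at
1 − 1e−6). The sign convention is case minus control — negative MDC means
loss of coordination in cases — and swapping the groups negates the value
exactly. Significance is a sample-label permutation null preserving group
sizes, two-sided, with the +1 correction:
p = (1 + #{|MDC_perm| ≥ |MDC_obs|})/(n_perm + 1). Pairs with a constant
feature in either group are dropped and counted. Identical case and
control sample lists short-circuit to MDC = 0 exactly.

**t-tests and q-values.** Classic equal-variance Student t by default
(Welch behind a flag). Storey q-values estimate π₀ on the λ grid
0.05..0.95 with a cubic-polynomial smoother evaluated at λ = 0.95, falling
back to BH (π₀ = 1) below 100 features or when the estimate leaves (0, 1].

**Count filter.** A gene is removed iff it has fewer than `min_count`
(default 100) counts in at least `sample_fraction` (default 0.8) of
samples; boundary cases are covered by tests (exactly 100 counts is not
"fewer than"; 3/5 low samples is below the 0.8 fraction).

**Moderated DEG pipeline.** log₂ CPM with the (count + 0.5)/(lib + 1)
offset; an unweighted per-gene fit provides residual SDs whose square
roots are lowess-smoothed (span 0.5) against mean log₂ count; the trend,
evaluated at each observation's fitted log-count, gives inverse
fourth-power weights; weighted least squares per gene; empirical-Bayes
variance shrinkage with the prior (d₀, s₀²) fitted by method of moments on
log s² (trigamma inversion by bisection); moderated t with d₀ + d_resid
degrees of freedom; BH FDR. The DEG signature requires both p < 0.05 and
FDR < 0.3. On identical NB data this implementation reproduces R
limma-voom's calls, power and prior df to the reported precision. Note
that CPM normalization makes fold-change estimates compositional: with
many strongly induced genes the library inflates and the per-gene log₂ FC
shrinks accordingly (e.g. 4-fold changes in 100 of 500 genes appear as
log₂(4/1.6) ≈ 1.32); tests account for this.

## Pipeline and formats

The orchestrated pipeline (simulate → coexpress per region → annotate →
merge → learn per-region networks → union → KDA → knockout + DEG →
validate → MDC → multi-set comparison) is fully seeded from one config:
two runs with the same config produce byte-identical outputs. Each output
table is stamped with its generating stage and a config hash computed over
analysis parameters only (not the output path). A JSON manifest records
stage, outputs, seed, runtime, and failures with the failing stage's name;
stages whose outputs exist can be resumed from disk.

Formats are deliberately plain: TSV for matrices and tables (feature-id
first column, comment lines allowed), GMT for gene sets, 3-column TSV edge
lists for networks. Identifiers are case-sensitive human-style symbols;
mouse-case symbols are harmonized on ingest by case-insensitive match,
with misses logged and counted (homology-based mapping is out of scope).

## Problem sizes

Tests and the acceptance script run at desk scale by choice: 20-node
structure-recovery problems (n=500, 10 seeds), 100-gene two-block module
recovery (n=500), 200-gene knockout experiments at 6 samples/group,
2000-gene DEG calibrations over 20 seeds, 200 null repeats × 1000
permutations for MDC calibration, and a 120-gene three-region pipeline for
the determinism check. These sizes give stable pass/fail behavior for the
statistical properties being asserted while keeping any single check in
the minutes range.

## Known limitations

- The static tree cut requires a sensible cut height; very fine structure
  that dynamic tree cutting would resolve may be merged or discarded.
- The BN learner targets module-sized problems (≲ 200 genes); the
  per-sweep cost grows quadratically in gene count.
- Orientation of edges that are neither prior-anchored nor constrained by
  v-structures is decided by score noise/tie-breaks and is expected to be
  ~50% accurate; only the prior-informative subset carries an accuracy
  guarantee.
- The permutation MDC p-value floor is 1/(n_perm + 1); claims below that
  resolution require more permutations.
- Storey's π₀ smoother can be unstable for small feature counts; the BH
  fallback is conservative.
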