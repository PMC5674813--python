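# olnet

Multiscale gene-network analysis for expression, genetic and proteomic
data, modeled on the systems-biology workflow used to dissect
oligodendrocyte (OL) and myelination networks in Alzheimer's disease:
weighted coexpression modules merged into a core gene set, Bayesian causal
networks oriented by cis-eQTL priors, key driver calling with
perturbation-based topology validation, modular differential connectivity,
and count-based differential expression.

The package is aimed at computational biologists who want each of these
stages as a tested, importable building block. Every stage is exercised
end to end on a bundled synthetic-data generator that plants the structure
the analysis is supposed to recover (modular regulatory DAGs with
designated hub genes, cis-eSNP dosage effects, knockout count data,
Braak-stratified proteomics-like matrices), so the whole pipeline is
verifiable without any external download.

## Methods at a glance

- **Coexpression** (`olnet.coexpression`): unsigned weighted network
  a_ij = |cor(x_i, x_j)|^β with β chosen by the scale-free topology
  criterion (signed R² of log₁₀ freq(k) on log₁₀ k); topological overlap
  TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij); modules by
  average-linkage clustering of 1 − TOM with a static branch cut, labels
  from a fixed color list by descending size; region-specific modules merge
  by set union into a core gene set.
- **Enrichment** (`olnet.enrichment`): one-sided Fisher exact tests with
  fold enrichment FE = (k/|A|)/(|B|/|U|); Benjamini–Hochberg adjustment;
  module × cell-type annotation matrices; GO-style enrichment with a strict
  term-size window (100 < |term| < 800); an exact m-way set-intersection
  test computed by iterated hypergeometric conditioning in log space
  (p-values of order 1e-80 remain representable).
- **Causal networks** (`olnet.bayesnet`): linear-Gaussian BIC hill
  climbing (add/delete/reverse) with iterated-local-search restarts,
  maximum in-degree 3; a cis-eSNP count prior penalizes orienting an edge
  into the gene with more eSNPs by ln 10, breaking Markov equivalence
  toward the anchored source; per-region DAGs merge by a set union of
  directed links that may carry reciprocal and parallel (multi-region)
  edges.
- **Key drivers** (`olnet.drivers`): score = size of the n-layer
  downstream neighborhood (directed BFS, default n = 5); key drivers are
  the top 40 by reach that also exceed mean + 1 SD; driver subnetworks are
  validated by layerwise Fisher enrichment of perturbation DEG signatures.
- **Differential** (`olnet.differential`): modular differential
  connectivity MDC = mean over module gene pairs of
  arctanh(r_case) − arctanh(r_control) with a sample-label permutation
  null; Student t-tests with Storey q-values; the "fewer than 100 counts in
  ≥ 80% of samples" gene filter; a voom/limma-style pipeline (log₂ CPM,
  lowess mean–variance trend, inverse-variance observation weights,
  empirical-Bayes moderated t) with signature gates p < 0.05 and FDR < 0.3.
- **Synthetic data** (`olnet.synthetic`): all generators are
  deterministic given their seed and return ground truth alongside data.

## Worked example

`examples/04_knockout_validation.py` ablates a planted hub gene, calls
DEGs from the simulated WT/KO counts and tests the signature against the
true network topology:

```
driver G0001: 12 libraries, 0 genes filtered
DEG signature: 42 genes (25 down-regulated)
layerwise enrichment of the KO signature in the driver's reach:
  layer 1: neighborhood  21, overlap  16, FE =  3.6, BH-adjusted p = 1.62e-08
  layer 2: neighborhood  43, overlap  24, FE =  2.7, BH-adjusted p = 1.39e-08
  layer 3: neighborhood  59, overlap  30, FE =  2.4, BH-adjusted p = 8.50e-10
  layer 4: neighborhood  72, overlap  31, FE =  2.1, BH-adjusted p = 2.53e-08
  layer 5: neighborhood  83, overlap  31, FE =  1.8, BH-adjusted p = 2.04e-06
```

The genes that respond to the knockout concentrate in the driver's
downstream neighborhoods at every depth — the computational signature of a
correct network topology. Fold enrichment decays with depth as the
neighborhood grows while the ablation effect attenuates, the same
qualitative shape the corresponding real-data analyses produce.

The other example scripts cover module detection
(`01_coexpression_modules.py`), enrichment statistics
(`02_enrichment_statistics.py`), causal network learning and key drivers
(`03_causal_network_and_drivers.py`), differential connectivity
(`05_differential_connectivity.py`) and the orchestrated pipeline
(`06_full_pipeline.py`). A thin CLI mirrors the pipeline stages:

```bash
olnet run --outdir demo --seed 7          # full pipeline
olnet simulate --outdir data --seed 1     # individual stages:
olnet coexpress --expr data/expression_PFC.tsv --beta auto --out modules.tsv
olnet kda --network bn_union.tsv --layers 5 --top 40 --out drivers.tsv
```

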