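"""Validate a driver's subnetwork with a simulated knockout experiment.

Ablates a planted hub gene, generates negative-binomial WT/KO counts with
effects propagating down the true regulatory network, applies the low-count
filter and the precision-weighted moderated-t DEG pipeline (signature gates
p < 0.05 and FDR < 0.3), then tests the signature's enrichment in the
driver's n-layer downstream neighborhoods.
"""
from olnet import (
    DirectedNetwork,
    Edge,
    SimulationConfig,
    filter_low_counts,
    generate_regulatory_network,
    simulate_knockout,
    validate_driver,
    voom_limma_deg,
)
from olnet.differential import signature_from_deg_table

truth = generate_regulatory_network(n_genes=200, n_modules=3, edges_per_gene=2.0, seed=0)
driver = truth.hub_by_module["M1"]
config = SimulationConfig(n_genes=200, seed=300)

counts, labels = simulate_knockout(truth, driver, config)
kept, removed = filter_low_counts(counts, min_count=100, sample_fraction=0.8)
print(f"driver {driver}: {counts.shape[1]} libraries, {len(removed)} genes filtered")

deg = voom_limma_deg(kept, labels, p_cut=0.05, fdr_cut=0.3)
signature = signature_from_deg_table(deg, driver=driver)
n_down = (signature.deg_table["direction"] == "down").sum()
print(f"DEG signature: {len(signature.genes)} genes ({n_down} down-regulated)")

network = DirectedNetwork(
    frozenset(truth.genes),
    [Edge(s, t, "truth") for s, t in truth.regulatory_dag.edges],
)
results = validate_driver(network, driver, signature, universe=truth.genes, n_max=5)
print("layerwise enrichment of the KO signature in the driver's reach:")
for i, r in enumerate(results, start=1):
    print(f"  layer {i}: neighborhood {r.set_b_size:3d}, overlap {r.overlap:3d}, "
          f"FE = {r.fold_enrichment:4.1f}, BH-adjusted p = {r.adjusted_p:.2e}")
# Significant enrichment at every layer supports the network topology: the
# genes that respond to the ablation sit downstream of the driver.
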