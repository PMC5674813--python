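"""Learn causal gene networks with eSNP priors and rank key drivers.

Per-region Bayesian networks are learned by BIC-scored hill climbing;
cis-eSNP counts act as orientation priors that break Markov equivalence
(the anchored gene is favored as the causal source). Region networks are
merged by a set union of directed links, and genes are ranked by 5-layer
downstream reach.
"""
from olnet import (
    BnConfig,
    SimulationConfig,
    generate_regulatory_network,
    key_driver_analysis,
    learn_bayesian_network,
    simulate_expression,
    union_networks,
)
from olnet.bayesnet import esnp_prior_from_truth

truth = generate_regulatory_network(n_genes=30, n_modules=2, edges_per_gene=1.2,
                                    seed=3, esnp_fraction=0.3)
config = SimulationConfig(n_genes=30, n_samples_per_region=400,
                          regions=("PFC", "CBM"), noise_sd=0.3, seed=3)
exprs, _ = simulate_expression(truth, config)
prior = esnp_prior_from_truth(truth.esnp_anchor)

nets = []
for region in config.regions:
    net = learn_bayesian_network(exprs[region], prior=prior,
                                 config=BnConfig(seed=3, restarts=50), region=region)
    true_edges = set(truth.regulatory_dag.edges)
    learned = {(e.source, e.target) for e in net.edges}
    tp = len(true_edges & learned)
    print(f"{region}: {net.n_edges} edges learned, {tp} match the planted DAG "
          f"(precision {tp / net.n_edges:.2f}, recall {tp / len(true_edges):.2f})")
    nets.append(net)

union = union_networks(nets)
print(f"union network: {union.n_edges} provenance edges over {len(union.nodes)} genes "
      f"(acyclic: {union.is_acyclic()})")
# the union keeps one record per region for shared edges and is not forced
# acyclic: disagreeing orientations become reciprocal edge pairs

drivers = key_driver_analysis(union, n_layers=5, top_n=5)
hubs = set(truth.hub_by_module.values())
print("top 5 by 5-layer downstream reach in the union:")
for r in drivers[:5]:
    mark = " <- planted hub" if r.gene in hubs else ""
    print(f"  rank {r.rank}: {r.gene} reaches {int(r.score)} genes"
          f" (key driver: {r.is_key_driver}){mark}")
# One planted hub is called a key driver outright; orientation errors in the
# learned networks let a few of its immediate downstream genes inherit most
# of its reach and rank alongside it — the union trades orientation
# precision for robustness, which is why perturbation-based validation of
# the called drivers (example 04) matters.
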