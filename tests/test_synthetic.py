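"""Generator contracts: planted structure, determinism, effect recovery."""
import networkx as nx
import numpy as np
import pytest
from scipy import stats

from olnet.datatypes import DirectedNetwork, Edge, GeneModule
from olnet.errors import ParameterError
from olnet.synthetic import (
    GroundTruth,
    SimulationConfig,
    generate_regulatory_network,
    knockout_log2_effects,
    simulate_expression,
    simulate_knockout,
    simulate_proteomics,
)


def _net(truth: GroundTruth) -> DirectedNetwork:
    return DirectedNetwork(
        frozenset(truth.genes),
        [Edge(s, t) for s, t in truth.regulatory_dag.edges],
    )


class TestGenerateRegulatoryNetwork:
    def test_no_edges_requested(self):
        t = generate_regulatory_network(2, 1, 0, seed=1)
        assert t.regulatory_dag.number_of_nodes() == 2
        assert t.regulatory_dag.number_of_edges() == 0

    @pytest.mark.parametrize("seed", [7, 11, 23])
    def test_acyclic(self, seed):
        t = generate_regulatory_network(50, 2, 2, seed=seed)
        assert nx.is_directed_acyclic_graph(t.regulatory_dag)
        # topological sort succeeds
        assert len(list(nx.topological_sort(t.regulatory_dag))) == 50

    def test_modules_partition_genes(self):
        t = generate_regulatory_network(50, 3, 2, seed=5)
        assert set(t.module_assignment) == set(t.genes)
        assert len(set(t.module_assignment.values())) == 3

    def test_hub_has_largest_downstream_neighborhood_in_module(self):
        # verified against exhaustive BFS over the generated DAG
        from olnet.drivers import downstream_neighborhood

        t = generate_regulatory_network(200, 3, 3, seed=11)
        net = _net(t)
        for mod, hub in t.hub_by_module.items():
            members = {g for g, m in t.module_assignment.items() if m == mod}
            sizes = {g: len(downstream_neighborhood(net, g, 5) & members) for g in members}
            assert sizes[hub] == max(sizes.values())
            # hub directly reaches >= 30% of the rest of its module
            direct = set(t.regulatory_dag.successors(hub)) & members
            assert len(direct) >= 0.3 * (len(members) - 1)

    def test_esnp_fraction_and_membership(self):
        t = generate_regulatory_network(100, 2, 1, seed=3, esnp_fraction=0.4)
        assert len(t.esnp_anchor) == 40
        assert set(t.esnp_anchor) <= set(t.genes)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ParameterError):
            generate_regulatory_network(2, 3, 1, seed=0)
        with pytest.raises(ParameterError):
            generate_regulatory_network(10, 2, -1, seed=0)

    def test_deterministic_given_seed(self):
        a = generate_regulatory_network(60, 2, 2, seed=9)
        b = generate_regulatory_network(60, 2, 2, seed=9)
        assert set(a.regulatory_dag.edges(data="effect")) == set(b.regulatory_dag.edges(data="effect"))
        assert a.esnp_anchor == b.esnp_anchor


class TestSimulateExpression:
    def test_independent_genes_uncorrelated(self):
        t = generate_regulatory_network(10, 1, 0, seed=2)
        cfg = SimulationConfig(n_genes=10, n_samples_per_region=2000, regions=("R",),
                               noise_sd=1.0, esnp_fraction=0.0, seed=4)
        ex, _ = simulate_expression(t, cfg)
        c = np.corrcoef(ex["R"].values.to_numpy())
        off = c[np.triu_indices(10, k=1)]
        assert np.all(np.abs(off) < 0.1)

    def test_chain_correlation_matches_signal_to_noise(self):
        # r ~ sqrt(1 / (1 + noise^2)) = 0.995 for effect 1, noise 0.1
        dag = nx.DiGraph()
        dag.add_edge("A", "B", effect=1.0)
        t = GroundTruth(dag, {"A": "M1", "B": "M1"}, {})
        cfg = SimulationConfig(n_genes=2, n_samples_per_region=1000, regions=("R",),
                               noise_sd=0.1, seed=3)
        ex, _ = simulate_expression(t, cfg)
        v = ex["R"].values
        assert np.corrcoef(v.loc["A"], v.loc["B"])[0, 1] > 0.9

    def test_esnp_slope_recovered_by_ols(self):
        dag = nx.DiGraph()
        dag.add_node("A")
        t = GroundTruth(dag, {"A": "M1"}, {"A": "rs1"})
        cfg = SimulationConfig(n_genes=1, n_samples_per_region=1000, regions=("R",),
                               noise_sd=1.0, esnp_effect=2.0, allele_freq=0.5, seed=5)
        ex, geno = simulate_expression(t, cfg)
        x = geno["R"].loc["rs1"].to_numpy()
        y = ex["R"].values.loc["A"].to_numpy()
        slope = np.polyfit(x, y, 1)[0]
        assert slope == pytest.approx(2.0, abs=0.2)

    def test_parent_child_slopes_within_3_se(self):
        t = generate_regulatory_network(15, 1, 1.5, seed=6)
        cfg = SimulationConfig(n_genes=15, n_samples_per_region=1000, regions=("R",),
                               noise_sd=0.5, esnp_fraction=0.0, seed=7)
        ex, _ = simulate_expression(t, cfg)
        v = ex["R"].values
        for s, tt, d in t.regulatory_dag.edges(data=True):
            others = [p for p in t.regulatory_dag.predecessors(tt)]
            X = v.loc[others].to_numpy().T
            res = stats.linregress(v.loc[s], v.loc[tt]) if len(others) == 1 else None
            if res is not None:
                assert abs(res.slope - d["effect"]) < 3 * res.stderr

    def test_intra_module_correlation_exceeds_inter(self):
        t = generate_regulatory_network(60, 2, 2, seed=8)
        cfg = SimulationConfig(n_genes=60, n_samples_per_region=500, regions=("R",), seed=9)
        ex, _ = simulate_expression(t, cfg)
        c = np.abs(np.corrcoef(ex["R"].values.to_numpy()))
        genes = ex["R"].feature_ids
        same = np.array([[t.module_assignment[a] == t.module_assignment[b] for b in genes] for a in genes])
        iu = np.triu_indices(len(genes), k=1)
        assert c[iu][same[iu]].mean() > c[iu][~same[iu]].mean()

    def test_cyclic_truth_rejected(self):
        dag = nx.DiGraph()
        dag.add_edge("A", "B", effect=1.0)
        dag.add_edge("B", "A", effect=1.0)
        with pytest.raises(ParameterError):
            GroundTruth(dag, {"A": "M1", "B": "M1"}, {})

    def test_deterministic_given_seed(self):
        t = generate_regulatory_network(20, 2, 1, seed=1)
        cfg = SimulationConfig(n_genes=20, n_samples_per_region=50, regions=("R",), seed=11)
        a, ga = simulate_expression(t, cfg)
        b, gb = simulate_expression(t, cfg)
        assert a["R"].values.equals(b["R"].values)
        assert ga["R"].equals(gb["R"])


class TestSimulateKnockout:
    def test_driver_counts_zero_in_ko(self):
        t = generate_regulatory_network(40, 2, 2, seed=4)
        hub = t.hub_by_module["M1"]
        counts, labels = simulate_knockout(t, hub, SimulationConfig(n_genes=40, seed=9))
        assert (counts.loc[hub, labels == "KO"] == 0).all()
        assert (counts.loc[hub, labels == "WT"] > 0).median()

    def test_unknown_driver_rejected(self):
        t = generate_regulatory_network(10, 1, 1, seed=0)
        with pytest.raises(KeyError):
            simulate_knockout(t, "NOT_A_GENE", SimulationConfig(n_genes=10))

    def test_null_gene_p_uniform_across_repeats(self):
        # two-node graph with no edge: the non-driver gene is null; its
        # two-sample t-test p-values should be uniform across repeats
        dag = nx.DiGraph()
        dag.add_nodes_from(["A", "B"])
        t = GroundTruth(dag, {"A": "M1", "B": "M1"}, {})
        ps = []
        for rep in range(200):
            cfg = SimulationConfig(n_genes=2, nb_dispersion=0.1, seed=1000 + rep,
                                   n_ko_per_group=8)
            counts, labels = simulate_knockout(t, "A", cfg)
            y = np.log2(counts.loc["B"].to_numpy(dtype=float) + 1)
            ps.append(stats.ttest_ind(y[labels == "KO"], y[labels == "WT"]).pvalue)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_propagated_effect_decays_along_chain(self):
        dag = nx.DiGraph()
        dag.add_edge("D", "X", effect=1.0)
        dag.add_edge("X", "Y", effect=1.0)
        t = GroundTruth(dag, dict.fromkeys("DXY", "M1"), {})
        lfc_x, lfc_y = [], []
        for seed in range(8):
            cfg = SimulationConfig(n_genes=3, attenuation=0.5, knockout_effect=-2.0,
                                   seed=seed, n_ko_per_group=10)
            delta = knockout_log2_effects(t, "D", cfg)
            assert delta["X"] == -1.0 and delta["Y"] == -0.5
            counts, labels = simulate_knockout(t, "D", cfg)
            y = np.log2(counts.astype(float) + 1)
            lfc_x.append(y.loc["X", labels == "KO"].mean() - y.loc["X", labels == "WT"].mean())
            lfc_y.append(y.loc["Y", labels == "KO"].mean() - y.loc["Y", labels == "WT"].mean())
        assert abs(np.mean(lfc_x)) > abs(np.mean(lfc_y)) > 0


class TestSimulateProteomics:
    def test_singleton_module_rejected(self):
        with pytest.raises(ParameterError):
            simulate_proteomics(GeneModule("m", frozenset(["only"])), 10, 0.5, 0.5, seed=0)
        # frozen dataclass check is in GeneModule: empty set also rejected
        with pytest.raises(ParameterError):
            GeneModule("m", frozenset())

    def test_invalid_correlations_rejected(self):
        mod = GeneModule("m", frozenset(["a", "b", "c"]))
        with pytest.raises(ParameterError):
            simulate_proteomics(mod, 10, 0.2, 0.6, seed=0)  # r_case > r_control
        with pytest.raises(ParameterError):
            simulate_proteomics(mod, 10, 0.5, -0.9, seed=0)  # not positive definite

    def test_planted_correlations_and_labels(self):
        mod = GeneModule("m", frozenset(f"p{i}" for i in range(10)))
        em = simulate_proteomics(mod, 500, 0.6, 0.2, seed=5)
        meta = em.sample_meta
        assert set(meta["group"]) == {"0-2", "5-6"}
        sub = em.values.loc[sorted(mod.members)]
        for grp, target in (("0-2", 0.6), ("5-6", 0.2)):
            ids = meta.index[meta["group"] == grp]
            c = np.corrcoef(sub[ids].to_numpy())
            mean_r = c[np.triu_indices(10, k=1)].mean()
            assert mean_r == pytest.approx(target, abs=0.08)

    def test_background_uncorrelated_with_module(self):
        mod = GeneModule("m", frozenset(f"p{i}" for i in range(5)))
        em = simulate_proteomics(mod, 400, 0.6, 0.6, seed=1, n_background=5)
        mod_vals = em.values.loc[sorted(mod.members)].to_numpy()
        bg_vals = em.values.loc[[i for i in em.feature_ids if i.startswith("BG")]].to_numpy()
        cross = np.corrcoef(mod_vals, bg_vals)[:5, 5:]
        assert np.abs(cross).max() < 0.2
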