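"""End-to-end orchestration on synthetic data.

``run_pipeline`` executes the full analysis in order: simulate inputs,
build per-region coexpression networks and modules, annotate modules
against cell-type markers, merge the top-annotated modules into a core gene
set, learn per-region causal networks with eSNP priors over the core genes,
union them, run key driver analysis, knock out the top planted hub and call
DEGs, validate the driver's subnetwork layer by layer, measure modular
differential connectivity on a proteomics-like contrast, and compare
direction-stratified signatures by the exact multi-set test.

Every stage is seeded from the config, writes its outputs under the run
directory (stamped with the stage name and config hash), and is recorded in
a JSON manifest. Reruns with ``resume=True`` skip stages whose outputs
already exist by reloading them.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as olio
from .bayesnet import BnConfig, esnp_prior_from_truth, learn_bayesian_network, union_networks
from .coexpression import (
    adjacency_from_correlation,
    cluster_modules,
    correlation_matrix,
    merge_modules,
    pick_soft_threshold,
    topological_overlap,
)
from .datatypes import GeneModule, GeneSet
from .differential import (
    compare_signatures,
    filter_low_counts,
    modular_differential_connectivity,
    signature_from_deg_table,
    voom_limma_deg,
)
from .drivers import key_driver_analysis, key_driver_table, validate_driver, validation_table
from .enrichment import celltype_annotation
from .errors import ParameterError
from .synthetic import (
    GroundTruth,
    SimulationConfig,
    generate_regulatory_network,
    simulate_expression,
    simulate_knockout,
    simulate_proteomics,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All stage parameters plus paths; round-trips losslessly through YAML."""

    outdir: str = "olnet_run"
    seed: int = 0
    # simulation
    n_genes: int = 200
    n_modules: int = 3
    edges_per_gene: float = 2.0
    n_samples_per_region: int = 100
    regions: tuple[str, ...] = ("PFC", "VC", "CBM")
    noise_sd: float = 1.0
    esnp_fraction: float = 0.3
    esnp_effect: float = 1.0
    allele_freq: float = 0.3
    nb_dispersion: float = 0.1
    library_size_mean: int = 200_000
    n_ko_per_group: int = 6
    # coexpression
    beta: float | str = "auto"
    target_r2: float = 0.8
    min_module_size: int = 10
    cut_height: float = 0.995
    annotation_min_module_size: int = 10
    # causal network
    bn_restarts: int = 4
    bn_max_in_degree: int = 3
    bn_prior_weight: float = 2.302585092994046  # ln 10
    bn_max_genes: int = 80
    # key drivers
    kda_layers: int = 5
    kda_top_n: int = 40
    # differential
    deg_p_cut: float = 0.05
    deg_fdr_cut: float = 0.3
    filter_min_count: int = 100
    filter_sample_fraction: float = 0.8
    mdc_n_perm: int = 1000
    proteomics_n_per_group: int = 100
    proteomics_r_control: float = 0.6
    proteomics_r_case: float = 0.2
    proteomics_module_size: int = 30
    # enrichment
    go_min_size: int = 100
    go_max_size: int = 800

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["regions"] = list(d["regions"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "regions" in d:
            d["regions"] = tuple(d["regions"])
        return cls(**d)

    def config_hash(self) -> str:
        # analysis parameters only: the output location does not change results
        d = dataclasses.asdict(self)
        d.pop("outdir")
        d["regions"] = list(d["regions"])
        return hashlib.sha1(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]

    def sim_config(self) -> SimulationConfig:
        return SimulationConfig(
            n_genes=self.n_genes,
            n_samples_per_region=self.n_samples_per_region,
            regions=tuple(self.regions),
            noise_sd=self.noise_sd,
            esnp_fraction=self.esnp_fraction,
            esnp_effect=self.esnp_effect,
            allele_freq=self.allele_freq,
            nb_dispersion=self.nb_dispersion,
            library_size_mean=self.library_size_mean,
            n_ko_per_group=self.n_ko_per_group,
            seed=self.seed,
        )


class _Manifest:
    def __init__(self, path: Path, config_hash: str):
        self.path = path
        self.config_hash = config_hash
        self.entries: list[dict] = []

    def record(self, stage: str, outputs: list[str], seed: int, t0: float, resumed: bool = False) -> None:
        self.entries.append(
            {
                "stage": stage,
                "outputs": outputs,
                "seed": seed,
                "runtime_s": round(time.perf_counter() - t0, 4),
                "resumed": resumed,
                "config_hash": self.config_hash,
            }
        )
        self.path.write_text(json.dumps(self.entries, indent=2))


def _truth_to_files(truth: GroundTruth, outdir: Path, stamp: dict) -> None:
    with open(outdir / "truth_edges.tsv", "w") as fh:
        fh.write(f"# stage=simulate config_hash={stamp['config_hash']}\n")
        fh.write("source\ttarget\teffect\n")
        for s, t, d in sorted(truth.regulatory_dag.edges(data=True)):
            fh.write(f"{s}\t{t}\t{d['effect']:.6g}\n")
    olio.write_gmt(
        [GeneSet(name=k, members=v) for k, v in sorted(truth.marker_membership.items())],
        outdir / "markers.gmt",
    )
    pd.DataFrame(
        sorted(truth.module_assignment.items()), columns=["gene", "module"]
    ).to_csv(outdir / "truth_modules.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.esnp_anchor.items()), columns=["gene", "esnp"]
    ).to_csv(outdir / "truth_esnps.tsv", sep="\t", index=False)


def _load_truth(outdir: Path) -> GroundTruth:
    import networkx as nx

    dag = nx.DiGraph()
    edges = pd.read_csv(outdir / "truth_edges.tsv", sep="\t", comment="#")
    mods = pd.read_csv(outdir / "truth_modules.tsv", sep="\t")
    dag.add_nodes_from(mods["gene"])
    for _, row in edges.iterrows():
        dag.add_edge(row["source"], row["target"], effect=float(row["effect"]))
    esnps = pd.read_csv(outdir / "truth_esnps.tsv", sep="\t")
    markers = {s.name: s.members for s in olio.read_gmt(outdir / "markers.gmt")}
    assignment = dict(zip(mods["gene"], mods["module"]))
    hubs: dict[str, str] = {}
    for g, m in sorted(assignment.items()):
        hubs.setdefault(m, g)  # hub is the first gene of each block by construction
    return GroundTruth(
        regulatory_dag=dag,
        module_assignment=assignment,
        esnp_anchor=dict(zip(esnps["gene"], esnps["esnp"])),
        marker_membership=markers,
        hub_by_module=hubs,
    )


def run_pipeline(config: PipelineConfig, resume: bool = False) -> Path:
    """Execute all stages; returns the run directory.

    Deterministic: identical config (hence identical seeds) gives bitwise-
    identical module membership files, edge lists, key-driver tables and DEG
    tables. With ``resume=True``, stages whose outputs already exist are
    reloaded from disk instead of recomputed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    stamp = {"config_hash": chash}
    logging.basicConfig(
        filename=outdir / "run.log", level=logging.INFO, force=False,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    config.to_yaml(outdir / "config.yaml")
    manifest = _Manifest(outdir / "manifest.json", chash)
    try:
        return _run_stages(config, outdir, chash, stamp, manifest, resume)
    except Exception as exc:
        manifest.entries.append(
            {"stage": getattr(manifest, "current", "unknown"), "error": str(exc),
             "config_hash": chash}
        )
        manifest.path.write_text(json.dumps(manifest.entries, indent=2))
        raise


def _run_stages(
    config: PipelineConfig, outdir: Path, chash: str, stamp: dict,
    manifest: _Manifest, resume: bool,
) -> Path:
    # --- simulate -----------------------------------------------------------
    manifest.current = "simulate"
    t0 = time.perf_counter()
    sim = config.sim_config()
    sim_files = [outdir / f"expression_{r}.tsv" for r in config.regions] + [
        outdir / "truth_edges.tsv", outdir / "truth_modules.tsv",
        outdir / "truth_esnps.tsv", outdir / "markers.gmt",
    ]
    resumed_sim = resume and all(f.exists() for f in sim_files)
    if resumed_sim:
        truth = _load_truth(outdir)
        exprs = {
            r: olio.read_expression_tsv(outdir / f"expression_{r}.tsv")
            for r in config.regions
        }
    else:
        truth = generate_regulatory_network(
            config.n_genes, config.n_modules, config.edges_per_gene,
            seed=config.seed, esnp_fraction=config.esnp_fraction,
        )
        exprs, genos = simulate_expression(truth, sim)
        _truth_to_files(truth, outdir, stamp)
        for region in config.regions:
            olio.write_expression_tsv(exprs[region], outdir / f"expression_{region}.tsv",
                                      stage="simulate", config_hash=chash)
            olio.write_expression_tsv(genos[region], outdir / f"genotypes_{region}.tsv",
                                      stage="simulate", config_hash=chash)
    manifest.record("simulate",
                    [f"expression_{r}.tsv" for r in config.regions] + ["truth_edges.tsv"],
                    config.seed, t0, resumed=resumed_sim)

    # --- coexpress per region ----------------------------------------------
    manifest.current = "coexpress"
    t0 = time.perf_counter()
    region_modules: dict[str, list[GeneModule]] = {}
    mod_files = [outdir / f"modules_{r}.tsv" for r in config.regions]
    resumed_coexp = resume and all(f.exists() for f in mod_files)
    for region in config.regions:
        if resumed_coexp:
            tab = pd.read_csv(outdir / f"modules_{region}.tsv", sep="\t", comment="#")
            region_modules[region] = [
                GeneModule(label=lab, members=frozenset(grp["feature_id"]), region=region,
                           universe_size=config.n_genes)
                for lab, grp in tab.groupby("module", sort=True)
            ]
            continue
        corr = correlation_matrix(exprs[region])
        if config.beta == "auto":
            st = pick_soft_threshold(corr, target_r2=config.target_r2)
            beta = st.chosen_power
        else:
            beta = float(config.beta)
        adj = adjacency_from_correlation(corr, beta)
        tom = topological_overlap(adj)
        mods = cluster_modules(tom, min_module_size=config.min_module_size,
                               cut_height=config.cut_height, region=region)
        region_modules[region] = mods
        rows = [
            {"module": m.label, "feature_id": g}
            for m in mods
            for g in sorted(m.members)
        ]
        olio.write_table(pd.DataFrame(rows), outdir / f"modules_{region}.tsv",
                         stage="coexpress", config_hash=chash)
    manifest.record("coexpress", [f"modules_{r}.tsv" for r in config.regions],
                    config.seed, t0, resumed=resumed_coexp)

    # --- annotate and select the marker-enriched module per region ----------
    manifest.current = "annotate+merge"
    t0 = time.perf_counter()
    universe = truth.genes
    marker_sets = [GeneSet(name=k, members=v) for k, v in sorted(truth.marker_membership.items())]
    selected: list[GeneModule] = []
    for region in config.regions:
        mods = [m for m in region_modules[region] if m.label != "unassigned"]
        neglog, best = celltype_annotation(
            mods, marker_sets, universe, min_module_size=config.annotation_min_module_size
        )
        olio.write_table(neglog.reset_index(names="module"),
                         outdir / f"annotation_{region}.tsv",
                         stage="annotate", config_hash=chash)
        target = marker_sets[0].name
        pick_label = neglog[target].idxmax()
        selected.append(next(m for m in mods if m.label == pick_label))
    core = merge_modules(selected, label="core_set")
    olio.write_gene_list(core.members, outdir / "core_gene_set.txt")
    manifest.record("annotate+merge", ["core_gene_set.txt"], config.seed, t0)

    # --- causal networks per region, then union -----------------------------
    manifest.current = "bn-learn+union"
    t0 = time.perf_counter()
    prior = esnp_prior_from_truth(truth.esnp_anchor)
    bn_cfg = BnConfig(
        restarts=config.bn_restarts, max_in_degree=config.bn_max_in_degree,
        prior_weight=config.bn_prior_weight, seed=config.seed,
    )
    core_genes = sorted(core.members)[: config.bn_max_genes]
    bn_files = [outdir / f"bn_{r}.tsv" for r in config.regions] + [outdir / "bn_union.tsv"]
    resumed_bn = resume and all(f.exists() for f in bn_files)
    if resumed_bn:
        union = olio.read_edge_list(outdir / "bn_union.tsv")
    else:
        region_nets = []
        for region in config.regions:
            sub = exprs[region].subset_features(core_genes)
            net = learn_bayesian_network(sub, prior=prior, config=bn_cfg, region=region)
            if not net.is_acyclic():
                raise RuntimeError(f"per-region network for {region} is cyclic")
            region_nets.append(net)
            olio.write_edge_list(net, outdir / f"bn_{region}.tsv", stage="bn-learn", config_hash=chash)
        union = union_networks(region_nets)
        olio.write_edge_list(union, outdir / "bn_union.tsv", stage="bn-union", config_hash=chash)
    manifest.record("bn-learn+union", ["bn_union.tsv"], config.seed, t0, resumed=resumed_bn)

    # --- key driver analysis -------------------------------------------------
    manifest.current = "kda"
    t0 = time.perf_counter()
    kda = key_driver_analysis(union, n_layers=config.kda_layers, top_n=config.kda_top_n)
    kda_tab = key_driver_table(kda)
    olio.write_table(kda_tab, outdir / "key_drivers.tsv", stage="kda", config_hash=chash)
    manifest.record("kda", ["key_drivers.tsv"], config.seed, t0)

    # --- knockout + DEG ------------------------------------------------------
    manifest.current = "knockout+deg"
    t0 = time.perf_counter()
    driver = truth.hub_by_module[sorted(truth.hub_by_module)[0]]
    counts, labels = simulate_knockout(truth, driver, sim)
    kept, removed = filter_low_counts(
        counts, min_count=config.filter_min_count, sample_fraction=config.filter_sample_fraction
    )
    deg = voom_limma_deg(kept, labels, p_cut=config.deg_p_cut, fdr_cut=config.deg_fdr_cut,
                         contrast=f"{driver}_KO_vs_WT")
    olio.write_table(deg, outdir / "deg_table.tsv", stage="deg", config_hash=chash)
    signature = signature_from_deg_table(deg, driver=driver)
    manifest.record("knockout+deg", ["deg_table.tsv"], config.seed, t0)

    # --- validate driver against the true network ----------------------------
    manifest.current = "validate-driver"
    t0 = time.perf_counter()
    from .datatypes import DirectedNetwork, Edge

    truth_net = DirectedNetwork(
        nodes=frozenset(truth.genes),
        edges=[Edge(s, t, "truth") for s, t in truth.regulatory_dag.edges],
    )
    val = validate_driver(truth_net, driver, signature, universe=truth.genes,
                          n_max=config.kda_layers)
    olio.write_table(validation_table(val), outdir / "driver_validation.tsv",
                     stage="validate-driver", config_hash=chash)
    manifest.record("validate-driver", ["driver_validation.tsv"], config.seed, t0)

    # --- proteomics MDC -------------------------------------------------------
    manifest.current = "mdc"
    t0 = time.perf_counter()
    prot_members = sorted(core.members)[: config.proteomics_module_size]
    if len(prot_members) < 2:
        raise ParameterError("core set too small for the proteomics contrast")
    prot_module = GeneModule(label="OL_protein", members=frozenset(prot_members))
    prot = simulate_proteomics(
        prot_module, config.proteomics_n_per_group,
        config.proteomics_r_control, config.proteomics_r_case, seed=config.seed + 1,
    )
    case_ids = list(prot.sample_meta.index[prot.sample_meta["group"] == "5-6"])
    control_ids = list(prot.sample_meta.index[prot.sample_meta["group"] == "0-2"])
    mdc = modular_differential_connectivity(
        prot, prot_module, case_ids, control_ids, n_perm=config.mdc_n_perm, seed=config.seed,
    )
    olio.write_table(
        pd.DataFrame([{
            "module": mdc.module, "mdc": mdc.mdc_value, "p": mdc.permutation_p,
            "n_case": mdc.n_case, "n_control": mdc.n_control,
            "n_perm": mdc.n_permutations,
        }]),
        outdir / "mdc.tsv", stage="mdc", config_hash=chash,
    )
    manifest.record("mdc", ["mdc.tsv"], config.seed, t0)

    # --- compartment comparison ----------------------------------------------
    manifest.current = "compare"
    t0 = time.perf_counter()
    down = signature.directional("down")
    from .drivers import downstream_neighborhood

    hood = downstream_neighborhood(truth_net, driver, config.kda_layers)
    compartment = truth.marker_membership[sorted(truth.marker_membership)[0]]
    try:
        comp = compare_signatures(
            [GeneSet("down_DEG", frozenset(down)), GeneSet("downstream", hood)],
            compartment=GeneSet("compartment", compartment),
            universe=truth.genes,
        )
        comp_row = {
            "sets": "down_DEG,downstream,compartment",
            "observed": comp.overlap, "expected": comp.expected,
            "fold_enrichment": comp.fold_enrichment, "p": comp.p_value,
        }
    except ParameterError as exc:
        comp_row = {"sets": "down_DEG,downstream,compartment", "error": str(exc)}
    olio.write_table(pd.DataFrame([comp_row]), outdir / "compartment_comparison.tsv",
                     stage="compare", config_hash=chash)
    manifest.record("compare", ["compartment_comparison.tsv"], config.seed, t0)

    return outdir
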