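"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator plants everything the downstream stages are supposed to
recover: a modular ground-truth regulatory DAG with one designated hub
("key driver") per module, linear-Gaussian expression driven by that DAG
with cis-eSNP dosage effects anchoring causal direction, negative-binomial
WT/KO count data in which ablation effects propagate down directed paths
with per-edge attenuation, and an equicorrelated proteomics-like matrix
with a planted loss of intra-module correlation in the AD (Braak 5-6)
group.

All generators are deterministic given their seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneModule
from .errors import ParameterError

__all__ = [
    "GroundTruth",
    "SimulationConfig",
    "generate_regulatory_network",
    "simulate_expression",
    "simulate_knockout",
    "simulate_proteomics",
]


@dataclass
class GroundTruth:
    """The planted regulatory structure downstream stages try to recover.

    ``regulatory_dag`` carries a signed ``effect`` attribute on every edge;
    ``module_assignment`` partitions the gene universe (label per gene);
    ``esnp_anchor`` maps a subset of genes to a cis-eSNP identifier;
    ``hub_by_module`` names the designated key driver of each module;
    ``marker_membership`` maps cell-type labels to marker gene sets.
    """

    regulatory_dag: nx.DiGraph
    module_assignment: dict[str, str]
    esnp_anchor: dict[str, str]
    marker_membership: dict[str, frozenset[str]] = field(default_factory=dict)
    hub_by_module: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.regulatory_dag):
            raise ParameterError("regulatory graph contains a directed cycle")
        for g in self.esnp_anchor:
            if g not in self.regulatory_dag:
                raise ParameterError(f"eSNP-anchored gene {g!r} not in network")

    @property
    def genes(self) -> list[str]:
        return sorted(self.regulatory_dag.nodes)

    def effect(self, source: str, target: str) -> float:
        return float(self.regulatory_dag.edges[source, target]["effect"])


@dataclass
class SimulationConfig:
    """Study conditions for the expression / count simulators.

    Defaults emulate a desk-scale version of a multi-region brain cohort:
    three regions, 100 samples each, unit-variance gene noise, 30% of genes
    with a cis-eSNP of effect 1.0 at minor-allele frequency 0.3, and
    RNA-seq-like NB counts (dispersion 0.1) at ~2e5 reads per library.
    """

    n_genes: int = 200
    n_samples_per_region: int = 100
    regions: tuple[str, ...] = ("PFC", "VC", "CBM")
    noise_sd: float = 1.0
    esnp_fraction: float = 0.3
    esnp_effect: float = 1.0
    allele_freq: float = 0.3
    nb_dispersion: float = 0.1
    library_size_mean: int = 200_000
    attenuation: float = 0.5
    knockout_effect: float = -2.0
    n_ko_per_group: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_samples_per_region <= 0:
            raise ParameterError("counts must be positive")
        if not 0.0 <= self.esnp_fraction <= 1.0:
            raise ParameterError("esnp_fraction must be in [0,1]")
        if not 0.0 < self.allele_freq < 1.0:
            raise ParameterError("allele_freq must be in (0,1)")
        if self.nb_dispersion <= 0:
            raise ParameterError("nb_dispersion must be > 0")
        if self.library_size_mean <= 0:
            raise ParameterError("library_size_mean must be positive")


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_regulatory_network(
    n_genes: int,
    n_modules: int,
    edges_per_gene: float,
    seed: int,
    esnp_fraction: float = 0.3,
    intra_module_prob: float = 0.85,
    hub_coverage: float = 0.3,
    marker_fraction: float = 0.6,
    max_in_degree: int = 3,
) -> GroundTruth:
    """Plant a modular regulatory DAG with one designated hub per module.

    Genes are laid out in a fixed topological order; modules are contiguous
    blocks in that order so intra-module edges always point forward. Each
    module's first gene is its hub and receives direct out-edges to at least
    ``hub_coverage`` of the module, making it a plantable key driver. The
    remaining edges are drawn per-gene (Poisson with mean ``edges_per_gene``)
    preferentially within the module. Edge effects are signed, with
    magnitudes uniform on [0.5, 1.5]. A fraction of genes receive cis-eSNP
    anchors; per-module marker gene sets emulate cell-type signatures.
    """
    if n_genes < 1 or n_modules < 1 or n_genes < n_modules:
        raise ParameterError("need n_genes >= n_modules >= 1")
    if edges_per_gene < 0:
        raise ParameterError("edges_per_gene must be >= 0")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)

    # contiguous module blocks in topological order
    bounds = np.linspace(0, n_genes, n_modules + 1).astype(int)
    module_of: dict[str, str] = {}
    blocks: dict[str, list[str]] = {}
    for m in range(n_modules):
        label = f"M{m + 1}"
        blocks[label] = genes[bounds[m]:bounds[m + 1]]
        for g in blocks[label]:
            module_of[g] = label

    dag = nx.DiGraph()
    dag.add_nodes_from(genes)
    hubs: dict[str, str] = {}

    def _add_edge(src: str, tgt: str) -> None:
        # genes have few direct regulators; cap the in-degree
        if src == tgt or dag.has_edge(src, tgt) or dag.in_degree(tgt) >= max_in_degree:
            return
        effect = float(rng.uniform(0.5, 1.5) * rng.choice([-1.0, 1.0]))
        dag.add_edge(src, tgt, effect=effect)

    if edges_per_gene > 0:
        for label, block in blocks.items():
            hub = block[0]
            hubs[label] = hub
            rest = block[1:]
            n_direct = int(np.ceil(hub_coverage * len(rest))) if rest else 0
            targets = rng.choice(len(rest), size=n_direct, replace=False) if n_direct else []
            for t in sorted(targets):
                _add_edge(hub, rest[t])
        index_of = {g: i for i, g in enumerate(genes)}
        for g in genes:
            k = rng.poisson(edges_per_gene)
            label = module_of[g]
            block = blocks[label]
            later_intra = [x for x in block if index_of[x] > index_of[g]]
            later_any = genes[index_of[g] + 1:]
            for _ in range(k):
                pool = later_intra if (later_intra and rng.random() < intra_module_prob) else later_any
                if not pool:
                    break
                _add_edge(g, pool[int(rng.integers(len(pool)))])
    else:
        for label, block in blocks.items():
            hubs[label] = block[0]

    n_anchor = int(round(esnp_fraction * n_genes))
    anchored = rng.choice(n_genes, size=n_anchor, replace=False)
    esnp_anchor = {genes[i]: f"rs_{genes[i]}" for i in sorted(anchored)}

    markers: dict[str, frozenset[str]] = {}
    for m, (label, block) in enumerate(blocks.items()):
        n_mark = max(1, int(round(marker_fraction * len(block))))
        chosen = rng.choice(len(block), size=n_mark, replace=False)
        markers[f"celltype_{m + 1}"] = frozenset(block[i] for i in sorted(chosen))

    return GroundTruth(
        regulatory_dag=dag,
        module_assignment=module_of,
        esnp_anchor=esnp_anchor,
        marker_membership=markers,
        hub_by_module=hubs,
    )


def simulate_expression(
    truth: GroundTruth, config: SimulationConfig
) -> tuple[dict[str, ExpressionMatrix], dict[str, pd.DataFrame]]:
    """Linear-Gaussian expression from the planted DAG, one matrix per region.

    Each gene is the effect-weighted sum of its parents plus Gaussian noise
    (``noise_sd``); eSNP-anchored genes additionally receive
    ``esnp_effect`` x dosage, with dosages Binomial(2, allele_freq)
    (Hardy-Weinberg). Returns per-region expression matrices and per-region
    genotype dosage matrices (SNPs x samples, values in {0,1,2}).
    """
    if not nx.is_directed_acyclic_graph(truth.regulatory_dag):
        raise ParameterError("truth graph must be acyclic")
    rng = np.random.default_rng(config.seed)
    genes = truth.genes
    order = list(nx.topological_sort(truth.regulatory_dag))
    n = config.n_samples_per_region
    exprs: dict[str, ExpressionMatrix] = {}
    genos: dict[str, pd.DataFrame] = {}
    anchored = sorted(truth.esnp_anchor)

    for region in config.regions:
        samples = [f"{region}_S{i:04d}" for i in range(1, n + 1)]
        dosage = pd.DataFrame(
            rng.binomial(2, config.allele_freq, size=(len(anchored), n)),
            index=[truth.esnp_anchor[g] for g in anchored],
            columns=samples,
        )
        vals: dict[str, np.ndarray] = {}
        for g in order:
            # root genes have unit variance; regulated genes add residual
            # noise of SD noise_sd on top of the parent signal
            parents = list(truth.regulatory_dag.predecessors(g))
            sd = config.noise_sd if parents else 1.0
            x = rng.normal(0.0, sd, size=n)
            for p in parents:
                x = x + truth.effect(p, g) * vals[p]
            if g in truth.esnp_anchor:
                x = x + config.esnp_effect * dosage.loc[truth.esnp_anchor[g]].to_numpy()
            vals[g] = x
        values = pd.DataFrame(
            np.vstack([vals[g] for g in genes]), index=genes, columns=samples
        )
        meta = pd.DataFrame({"region": region, "group": "synthetic"}, index=samples)
        exprs[region] = ExpressionMatrix(values, meta)
        genos[region] = dosage
    return exprs, genos


def knockout_log2_effects(truth: GroundTruth, driver: str, config: SimulationConfig) -> dict[str, float]:
    """Propagated log2 fold effects of ablating ``driver``.

    The driver carries ``knockout_effect`` (log2); each directed edge passes
    ``attenuation`` x the parent effect on, signed by the edge's regulatory
    sign, so effects decay layer by layer. Genes with no directed path from
    the driver get 0.
    """
    if driver not in truth.regulatory_dag:
        raise KeyError(f"driver {driver!r} not in network")
    delta = {g: 0.0 for g in truth.genes}
    delta[driver] = config.knockout_effect
    for g in nx.topological_sort(truth.regulatory_dag):
        if g == driver:
            continue
        acc = 0.0
        for p in truth.regulatory_dag.predecessors(g):
            if delta[p] != 0.0:
                acc += config.attenuation * np.sign(truth.effect(p, g)) * delta[p]
        delta[g] = acc
    return delta


def simulate_knockout(
    truth: GroundTruth,
    driver: str,
    config: SimulationConfig,
    n_per_group: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Negative-binomial WT/KO count matrix for an ablation of ``driver``.

    KO samples have the driver's mean parameter set exactly to 0; downstream
    genes shift by the propagated log2 effects; unconnected genes are null.
    Counts are gamma-Poisson (NB) with ``nb_dispersion`` and per-sample
    library sizes jittered around ``library_size_mean``. Returns the count
    matrix (genes x samples) and a WT/KO label series.
    """
    if driver not in truth.regulatory_dag:
        raise KeyError(f"driver {driver!r} not in network")
    rng = np.random.default_rng(config.seed)
    genes = truth.genes
    m = n_per_group if n_per_group is not None else config.n_ko_per_group
    if m < 2:
        raise ParameterError("need at least 2 samples per group")

    base = 2.0 ** rng.uniform(7.5, 11.0, size=len(genes))  # ~180..2000 relative
    delta = knockout_log2_effects(truth, driver, config)
    ko_scale = np.array([2.0 ** np.clip(delta[g], -10, 10) for g in genes])
    mean_wt = base
    mean_ko = base * ko_scale
    mean_ko[genes.index(driver)] = 0.0

    samples = [f"WT_{i:02d}" for i in range(1, m + 1)] + [f"KO_{i:02d}" for i in range(1, m + 1)]
    labels = pd.Series(["WT"] * m + ["KO"] * m, index=samples, name="group")
    lib = rng.normal(config.library_size_mean, 0.1 * config.library_size_mean, size=2 * m)
    lib = np.clip(lib, 0.2 * config.library_size_mean, None)

    counts = np.zeros((len(genes), 2 * m), dtype=np.int64)
    shape = 1.0 / config.nb_dispersion
    # normalize both conditions by the WT total so that genes unaffected by
    # the ablation keep the same expected rate (no compositional bias)
    ref_total = mean_wt.sum()
    for j in range(2 * m):
        mu = (mean_wt if j < m else mean_ko).astype(float).copy()
        mu *= lib[j] / ref_total
        # gamma-Poisson: Gamma(1/phi, scale=mu*phi) then Poisson => NB(mu, phi)
        lam = np.where(mu > 0, rng.gamma(shape, np.maximum(mu, 1e-12) / shape), 0.0)
        counts[:, j] = rng.poisson(lam)
    return pd.DataFrame(counts, index=genes, columns=samples), labels


def simulate_proteomics(
    module: GeneModule,
    n_per_group: int,
    r_control: float,
    r_case: float,
    seed: int,
    n_background: int = 100,
) -> ExpressionMatrix:
    """Braak-labelled proteomics-like matrix with a planted correlation drop.

    Module features are equicorrelated Gaussian with pairwise correlation
    ``r_control`` in the non-AD group (Braak 0-2) and ``r_case`` in the AD
    group (Braak 5-6); background features are independent noise.
    """
    members = sorted(module.members)
    p = len(members)
    if p < 2:
        raise ParameterError("module must contain at least 2 features")
    if not (-1.0 < r_case <= r_control < 1.0):
        raise ParameterError("require -1 < r_case <= r_control < 1")
    for r in (r_control, r_case):
        if 1.0 + (p - 1) * r <= 0:
            raise ParameterError(
                f"equicorrelation r={r} not positive definite for {p} features"
            )
    rng = np.random.default_rng(seed)

    def _equicorr(r: float, n: int) -> np.ndarray:
        if r >= 0:
            common = rng.normal(size=n)
            indep = rng.normal(size=(p, n))
            return np.sqrt(r) * common + np.sqrt(1.0 - r) * indep
        cov = r * np.ones((p, p)) + (1.0 - r) * np.eye(p)
        chol = np.linalg.cholesky(cov)
        return chol @ rng.normal(size=(p, n))

    ctrl = _equicorr(r_control, n_per_group)
    case = _equicorr(r_case, n_per_group)
    module_vals = np.hstack([ctrl, case])
    bg = rng.normal(size=(n_background, 2 * n_per_group))

    samples = [f"CTRL_{i:03d}" for i in range(1, n_per_group + 1)] + [
        f"AD_{i:03d}" for i in range(1, n_per_group + 1)
    ]
    bg_ids = [f"BG{i:04d}" for i in range(1, n_background + 1)]
    values = pd.DataFrame(
        np.vstack([module_vals, bg]), index=members + bg_ids, columns=samples
    )
    meta = pd.DataFrame(
        {
            "region": "PFC",
            "group": ["0-2"] * n_per_group + ["5-6"] * n_per_group,
        },
        index=samples,
    )
    return ExpressionMatrix(values, meta)
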