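"""Core in-memory containers shared across the pipeline.

Expression data lives in a pandas DataFrame (features x samples) wrapped with
its sample metadata; gene collections are plain ``set``-backed dataclasses;
directed networks keep an explicit edge list with region-of-origin provenance
because the merged (union) network may contain reciprocal and parallel edges.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .errors import ParameterError


@dataclass
class ExpressionMatrix:
    """Features x samples matrix plus per-sample metadata.

    ``values`` is indexed by feature id (rows) and sample id (columns);
    ``sample_meta`` is indexed by sample id and typically carries ``region``,
    ``group`` (e.g. Braak stratum) and covariate columns.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ParameterError(f"duplicate feature id: {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ParameterError(f"duplicate sample id: {dup!r}")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ParameterError(
                f"samples absent from sample_meta: {sorted(missing)[:5]}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_features(self, features: Iterable[str]) -> "ExpressionMatrix":
        keep = [f for f in features if f in self.values.index]
        return ExpressionMatrix(self.values.loc[keep], self.sample_meta)

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        keep = [s for s in samples if s in self.values.columns]
        return ExpressionMatrix(self.values[keep], self.sample_meta.loc[keep])


@dataclass
class GeneSet:
    """Named gene collection with an optional declared background universe."""

    name: str
    members: frozenset[str]
    universe: frozenset[str] | None = None
    description: str = ""

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if self.universe is not None:
            self.universe = frozenset(self.universe)
            extra = self.members - self.universe
            if extra:
                raise ParameterError(
                    f"gene set {self.name!r}: members outside universe, "
                    f"e.g. {sorted(extra)[:3]}"
                )

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneModule:
    """Coexpression module: color-style label + member genes + region of origin."""

    label: str
    members: frozenset[str]
    region: str = "merged"
    universe_size: int | None = None

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.members:
            raise ParameterError(f"module {self.label!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    provenance: str = ""


@dataclass
class DirectedNetwork:
    """Directed gene network with per-edge region provenance.

    Per-region learned networks are DAGs; a union network may contain cycles
    and multiple provenance records for the same (source, target) pair.
    """

    nodes: frozenset[str]
    edges: list[Edge] = field(default_factory=list)
    key_driver_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = frozenset(self.nodes)
        for e in self.edges:
            if e.source not in self.nodes or e.target not in self.nodes:
                raise ParameterError(f"edge endpoint not in node set: {e}")

    def successors(self) -> dict[str, set[str]]:
        """Topological adjacency: parallel provenance edges count once."""
        adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for e in self.edges:
            adj[e.source].add(e.target)
        return adj

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((e.source, e.target) for e in self.edges)
        return g

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_digraph())

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class EnrichmentResult:
    """2x2 overlap statistics: counts, fold enrichment, exact and adjusted p."""

    set_a_size: int
    set_b_size: int
    universe_size: int
    overlap: int
    fold_enrichment: float
    p_value: float
    adjusted_p: float | None = None
    label: str = ""


@dataclass
class EsnpPrior:
    """Per-gene count of associated cis-eSNPs; absent genes count 0."""

    gene_to_esnp_count: Mapping[str, int]

    def count(self, gene: str) -> int:
        return int(self.gene_to_esnp_count.get(gene, 0))


@dataclass
class PerturbationSignature:
    """DEG table from ablating one driver gene in one region.

    ``deg_table`` columns: gene, log2_fc, p, fdr, direction (up/down/
    inconsistent); only rows passing the signature gates belong to ``genes``.
    """

    driver: str
    region: str
    deg_table: pd.DataFrame

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.deg_table["gene"])

    def directional(self, direction: str) -> frozenset[str]:
        t = self.deg_table
        return frozenset(t.loc[t["direction"] == direction, "gene"])


@dataclass
class KeyDriverResult:
    gene: str
    neighborhood_size_by_layer: dict[int, int]
    score: float
    rank: int
    is_key_driver: bool


@dataclass
class MDCResult:
    """Modular differential connectivity: mean pairwise difference in
    Fisher-z-transformed correlations (case minus control)."""

    module: str
    n_case: int
    n_control: int
    mdc_value: float
    n_permutations: int
    permutation_p: float
    seed: int
    n_pairs_used: int = 0
    n_pairs_dropped: int = 0
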