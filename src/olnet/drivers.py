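"""Key driver analysis and perturbation-based topology validation.

A key driver is a gene whose n-layer downstream neighborhood (directed
reach, default n = 5) is outsized: ranked by reach, called when inside the
top-N (default 40) and more than one standard deviation above the mean
reach. Driver subnetworks are validated by testing, layer by layer, whether
the DEG signature of perturbing the driver is enriched in the driver's
n-layer downstream neighborhood.
"""
from __future__ import annotations

from collections import deque
from typing import Iterable

import numpy as np
import pandas as pd

from .datatypes import DirectedNetwork, EnrichmentResult, KeyDriverResult, PerturbationSignature
from .enrichment import bh_adjust, fisher_enrichment
from .errors import ParameterError

__all__ = ["downstream_neighborhood", "key_driver_analysis", "validate_driver"]


def downstream_neighborhood(
    network: DirectedNetwork, gene: str, n_layers: int
) -> frozenset[str]:
    """Nodes reachable from ``gene`` within ``n_layers`` directed steps.

    The gene itself is excluded; cycles are handled by a visited set, so the
    traversal terminates on union networks with reciprocal edges. Parallel
    provenance edges count once.
    """
    if gene not in network.nodes:
        raise KeyError(f"gene {gene!r} not in network")
    if n_layers < 1:
        raise ParameterError("n_layers must be >= 1")
    adj = network.successors()
    seen = {gene}
    frontier = deque([(gene, 0)])
    out: set[str] = set()
    while frontier:
        node, d = frontier.popleft()
        if d == n_layers:
            continue
        for nxt in adj[node]:
            if nxt not in seen:
                seen.add(nxt)
                out.add(nxt)
                frontier.append((nxt, d + 1))
    return frozenset(out)


def key_driver_analysis(
    network: DirectedNetwork,
    n_layers: int = 5,
    top_n: int = 40,
) -> list[KeyDriverResult]:
    """Rank all genes by downstream reach and call key drivers.

    Score = size of the ``n_layers`` downstream neighborhood. Ties rank by
    out-degree (descending) then identifier. A gene is called a key driver
    when it ranks within ``top_n`` AND its score exceeds mean + 1 SD of all
    node scores.
    """
    if not network.nodes:
        raise ParameterError("empty network")
    adj = network.successors()
    per_layer: dict[str, dict[int, int]] = {}
    scores: dict[str, int] = {}
    for g in network.nodes:
        sizes = {
            n: len(downstream_neighborhood(network, g, n)) for n in range(1, n_layers + 1)
        }
        per_layer[g] = sizes
        scores[g] = sizes[n_layers]
    values = np.array(list(scores.values()), dtype=float)
    gate = values.mean() + values.std(ddof=0)
    ordered = sorted(scores, key=lambda g: (-scores[g], -len(adj[g]), g))
    results = []
    for rank, g in enumerate(ordered, start=1):
        results.append(
            KeyDriverResult(
                gene=g,
                neighborhood_size_by_layer=per_layer[g],
                score=float(scores[g]),
                rank=rank,
                is_key_driver=bool(rank <= top_n and scores[g] > gate),
            )
        )
    return results


def key_driver_table(results: list[KeyDriverResult]) -> pd.DataFrame:
    rows = [
        {
            "gene": r.gene,
            "score": r.score,
            "rank": r.rank,
            "is_key_driver": r.is_key_driver,
            **{f"layer_{n}": s for n, s in sorted(r.neighborhood_size_by_layer.items())},
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def validate_driver(
    network: DirectedNetwork,
    driver: str,
    signature: PerturbationSignature | Iterable[str],
    universe: Iterable[str],
    n_max: int = 5,
) -> list[EnrichmentResult]:
    """Layerwise enrichment of a perturbation DEG signature in the driver's
    downstream neighborhoods.

    For n = 1..n_max, Fisher test of the signature against the n-layer
    neighborhood within ``universe``; BH adjustment across the layer set.
    Cross-species symbols must be harmonized upstream (case-insensitive
    matching is available in :mod:`olnet.io`).
    """
    u = frozenset(universe)
    sig = (
        signature.genes if isinstance(signature, PerturbationSignature) else frozenset(signature)
    )
    sig &= u
    if not sig:
        raise ParameterError("signature empty after universe restriction")
    results: list[EnrichmentResult] = []
    for n in range(1, n_max + 1):
        hood = downstream_neighborhood(network, driver, n) & u
        if not hood:
            results.append(
                EnrichmentResult(
                    set_a_size=len(sig), set_b_size=0, universe_size=len(u),
                    overlap=0, fold_enrichment=0.0, p_value=1.0, label=f"layer_{n}",
                )
            )
            continue
        r = fisher_enrichment(sig, hood, u, label=f"layer_{n}")
        results.append(r)
    adj = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, adj):
        r.adjusted_p = q
    return results


def validation_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "layer": i + 1,
                "signature_size": r.set_a_size,
                "neighborhood_size": r.set_b_size,
                "universe_size": r.universe_size,
                "overlap": r.overlap,
                "fold_enrichment": r.fold_enrichment,
                "p_value": r.p_value,
                "adjusted_p": r.adjusted_p,
            }
            for i, r in enumerate(results)
        ]
    )
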