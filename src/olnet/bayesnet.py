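"""Bayesian gene regulatory network learning with cis-eSNP orientation priors.

Structure search is greedy hill climbing over DAGs (single-edge add, delete,
reverse) maximizing the BIC of the linear-Gaussian model, with random
restarts. Within a Markov equivalence class observational data cannot choose
the edge direction; the genetic prior breaks the tie: an edge oriented INTO
the gene with more associated cis-eSNPs is penalized by a configurable
log-prior, so anchored genes resolve as sources.

Local scores are computed from the sample covariance matrix: for node v with
parent set P the profiled residual variance is the Schur complement
S_vv - S_vP S_PP^{-1} S_Pv, giving
    score(v | P) = -n/2 * log(sigma^2_{v|P}) - 0.5 * log(n) * (|P| + 1).
Scores are likelihood-equivalent, so with prior weight 0 Markov-equivalent
structures tie exactly (up to floating point).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import DirectedNetwork, Edge, EsnpPrior, ExpressionMatrix
from .errors import InsufficientDataError, ParameterError

__all__ = ["BnConfig", "learn_bayesian_network", "union_networks", "esnp_prior_from_truth"]


@dataclass
class BnConfig:
    """Search hyperparameters for structure learning."""

    restarts: int = 200
    max_in_degree: int = 3
    prior_weight: float = float(np.log(10.0))
    max_iter: int = 2000
    min_samples: int = 10
    seed: int = 0
    min_improvement: float = 1e-9


class _Searcher:
    def __init__(self, cov: np.ndarray, n: int, prior_counts: np.ndarray, cfg: BnConfig):
        self.cov = cov
        self.n = n
        self.p = cov.shape[0]
        self.prior_counts = prior_counts
        self.cfg = cfg
        self._local_cache: dict[tuple[int, frozenset[int]], float] = {}

    def local_score(self, v: int, parents: frozenset[int]) -> float:
        key = (v, parents)
        hit = self._local_cache.get(key)
        if hit is not None:
            return hit
        if parents:
            idx = sorted(parents)
            s_pp = self.cov[np.ix_(idx, idx)]
            s_vp = self.cov[v, idx]
            try:
                beta = np.linalg.solve(s_pp, s_vp)
            except np.linalg.LinAlgError:
                beta = np.linalg.lstsq(s_pp, s_vp, rcond=None)[0]
            sigma2 = self.cov[v, v] - float(s_vp @ beta)
        else:
            sigma2 = self.cov[v, v]
        sigma2 = max(sigma2, 1e-12)
        score = -0.5 * self.n * np.log(sigma2) - 0.5 * np.log(self.n) * (len(parents) + 1)
        self._local_cache[key] = score
        return score

    def edge_prior(self, s: int, t: int) -> float:
        # penalize orienting into the gene with more eSNPs
        if self.prior_counts[t] > self.prior_counts[s]:
            return -self.cfg.prior_weight
        return 0.0

    def total_score(self, parents: list[frozenset[int]]) -> float:
        tot = sum(self.local_score(v, parents[v]) for v in range(self.p))
        tot += sum(
            self.edge_prior(s, v) for v in range(self.p) for s in parents[v]
        )
        return tot

    @staticmethod
    def _has_path(parents: list[frozenset[int]], src: int, dst: int) -> bool:
        """True if dst is reachable from src following child direction."""
        children: dict[int, list[int]] = {}
        for v, ps in enumerate(parents):
            for u in ps:
                children.setdefault(u, []).append(v)
        stack, seen = [src], {src}
        while stack:
            u = stack.pop()
            if u == dst:
                return True
            for w in children.get(u, ()):  # noqa: B905
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return False

    def hill_climb(self, parents: list[frozenset[int]]) -> tuple[list[frozenset[int]], float]:
        cfg = self.cfg
        score = self.total_score(parents)
        for _ in range(cfg.max_iter):
            best_delta = cfg.min_improvement
            best_move = None
            for s in range(self.p):
                for t in range(self.p):
                    if s == t:
                        continue
                    if s in parents[t]:
                        # delete s->t
                        delta = (
                            self.local_score(t, parents[t] - {s})
                            - self.local_score(t, parents[t])
                            - self.edge_prior(s, t)
                        )
                        if delta > best_delta:
                            best_delta, best_move = delta, ("del", s, t)
                        # reverse s->t (becomes t->s)
                        if len(parents[s]) < cfg.max_in_degree:
                            trimmed = [ps - {s} if v == t else ps for v, ps in enumerate(parents)]
                            if not self._has_path(trimmed, s, t):
                                delta = (
                                    self.local_score(t, parents[t] - {s})
                                    - self.local_score(t, parents[t])
                                    + self.local_score(s, parents[s] | {t})
                                    - self.local_score(s, parents[s])
                                    - self.edge_prior(s, t)
                                    + self.edge_prior(t, s)
                                )
                                if delta > best_delta:
                                    best_delta, best_move = delta, ("rev", s, t)
                    elif t not in parents[s]:
                        # add s->t
                        if len(parents[t]) >= cfg.max_in_degree:
                            continue
                        if self._has_path(parents, t, s):
                            continue
                        delta = (
                            self.local_score(t, parents[t] | {s})
                            - self.local_score(t, parents[t])
                            + self.edge_prior(s, t)
                        )
                        if delta > best_delta:
                            best_delta, best_move = delta, ("add", s, t)
            if best_move is None:
                break
            op, s, t = best_move
            if op == "add":
                parents[t] = parents[t] | {s}
            elif op == "del":
                parents[t] = parents[t] - {s}
            else:
                parents[t] = parents[t] - {s}
                parents[s] = parents[s] | {t}
            score += best_delta
        return parents, self.total_score(parents)


def esnp_prior_from_truth(esnp_anchor: dict[str, str]) -> EsnpPrior:
    """Prior with count 1 for every anchored gene (one cis-eSNP each)."""
    return EsnpPrior({g: 1 for g in esnp_anchor})


def learn_bayesian_network(
    expr: ExpressionMatrix | pd.DataFrame,
    prior: EsnpPrior | None = None,
    config: BnConfig | None = None,
    genotypes: pd.DataFrame | None = None,
    region: str = "",
) -> DirectedNetwork:
    """Learn a DAG over the features of ``expr`` (one module, one region).

    ``genotypes`` is accepted for interface completeness but enters only
    through the eSNP counts in ``prior``; dosages are not network nodes.
    Deterministic given ``config.seed``: restart 0 starts from the empty
    graph, later restarts from seeded random DAGs; the best-scoring final
    structure wins, score ties broken toward the earliest restart.
    """
    cfg = config or BnConfig()
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    genes = list(values.index)
    n = values.shape[1]
    if n < cfg.min_samples:
        raise InsufficientDataError(
            f"{n} samples < floor of {cfg.min_samples}; refusing to learn a network"
        )
    if len(genes) < 2:
        raise ParameterError("need at least two genes")
    x = values.to_numpy(dtype=float).T  # samples x genes
    x = (x - x.mean(axis=0)) / np.where(x.std(axis=0, ddof=0) == 0, 1.0, x.std(axis=0, ddof=0))
    cov = (x.T @ x) / n
    counts = np.array([(prior.count(g) if prior else 0) for g in genes], dtype=float)

    searcher = _Searcher(cov, n, counts, cfg)
    rng = np.random.default_rng(cfg.seed)
    p = len(genes)
    # iterated local search: climb from the empty graph, then repeatedly
    # perturb the incumbent (random deletions and valid reversals) and
    # re-climb, keeping the best-scoring structure
    best_parents, best_score = searcher.hill_climb([frozenset() for _ in range(p)])
    for r in range(max(0, cfg.restarts - 1)):
        if r % 4 == 3:
            # diversification: random sparse DAG along a random topological order
            order = rng.permutation(p)
            pos = np.empty(p, dtype=int)
            pos[order] = np.arange(p)
            prob = min(0.5, 2.0 / p)
            start = [set() for _ in range(p)]
            for t in range(p):
                cands = [s for s in range(p) if pos[s] < pos[t] and rng.random() < prob]
                start[t] = set(cands[: cfg.max_in_degree])
        else:
            # intensification: perturb the incumbent (delete/reverse a quarter)
            start = [set(ps) for ps in best_parents]
            edges = [(s, t) for t in range(p) for s in start[t]]
            rng.shuffle(edges)
            n_perturb = max(2, len(edges) // 4)
            for s, t in edges[:n_perturb]:
                start[t].discard(s)
                if rng.random() < 0.5 and len(start[s]) < cfg.max_in_degree:
                    trial = [frozenset(ps) for ps in start]
                    if not _Searcher._has_path(trial, s, t):
                        start[s].add(t)
        final, score = searcher.hill_climb([frozenset(ps) for ps in start])
        if score > best_score + 1e-12:
            best_score = score
            best_parents = [frozenset(ps) for ps in final]
    assert best_parents is not None

    edges = [
        Edge(genes[s], genes[t], region)
        for t in range(p)
        for s in sorted(best_parents[t])
    ]
    net = DirectedNetwork(nodes=frozenset(genes), edges=edges)
    if not net.is_acyclic():
        raise RuntimeError("internal error: learned structure contains a cycle")
    return net


def structure_scores(
    expr: ExpressionMatrix | pd.DataFrame,
    edge_lists: list[list[tuple[str, str]]],
    prior: EsnpPrior | None = None,
    config: BnConfig | None = None,
) -> list[float]:
    """Penalized score of explicit candidate structures (diagnostic surface).

    Used to verify likelihood equivalence: with prior weight 0 the two
    orientations of a Markov-equivalent pair score identically.
    """
    cfg = config or BnConfig()
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    genes = list(values.index)
    index = {g: i for i, g in enumerate(genes)}
    n = values.shape[1]
    x = values.to_numpy(dtype=float).T
    x = (x - x.mean(axis=0)) / np.where(x.std(axis=0, ddof=0) == 0, 1.0, x.std(axis=0, ddof=0))
    cov = (x.T @ x) / n
    counts = np.array([(prior.count(g) if prior else 0) for g in genes], dtype=float)
    searcher = _Searcher(cov, n, counts, cfg)
    out = []
    for edges in edge_lists:
        parents = [frozenset() for _ in genes]
        for s, t in edges:
            parents[index[t]] = parents[index[t]] | {index[s]}
        out.append(searcher.total_score(parents))
    return out


def union_networks(networks: list[DirectedNetwork]) -> DirectedNetwork:
    """Set union of directed links across region-specific networks.

    Exact duplicates (same source, target, provenance) collapse; the same
    topological edge from different regions keeps one record per region.
    The union is not forced acyclic: reciprocal edges are legitimate.
    """
    if not networks:
        raise ParameterError("need at least one network")
    nodes = frozenset().union(*(n.nodes for n in networks))
    seen: set[tuple[str, str, str]] = set()
    edges: list[Edge] = []
    for net in networks:
        for e in net.edges:
            key = (e.source, e.target, e.provenance)
            if key not in seen:
                seen.add(key)
                edges.append(e)
    return DirectedNetwork(nodes=nodes, edges=edges)
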