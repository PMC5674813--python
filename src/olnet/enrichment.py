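"""Gene-set statistics.

All enrichments are one-sided (over-enrichment) Fisher exact tests under
hypergeometric sampling, with fold enrichment
FE = (overlap/|A|) / (|B|/|U|). Multiple testing uses Benjamini-Hochberg;
the scope of the adjustment differs by analysis and is stated per function.
The m-way intersection test computes the exact null distribution of the
intersection size of m independently drawn sets by iterated hypergeometric
conditioning, in log space so that p-values far below float underflow of
naive products (e.g. 1e-87) remain representable.
"""
from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .datatypes import EnrichmentResult, GeneModule, GeneSet
from .errors import ParameterError

__all__ = [
    "fisher_enrichment",
    "bh_adjust",
    "celltype_annotation",
    "go_enrichment",
    "multiset_intersection_test",
    "MultiSetResult",
]


def _as_set(s: GeneSet | Iterable[str]) -> frozenset[str]:
    return s.members if isinstance(s, GeneSet) else frozenset(s)


def fold_enrichment(overlap: int, size_a: int, size_b: int, universe_size: int) -> float:
    if size_a == 0 or size_b == 0:
        raise ParameterError("fold enrichment undefined for empty sets")
    return (overlap / size_a) / (size_b / universe_size)


def fisher_enrichment(
    set_a: GeneSet | Iterable[str],
    set_b: GeneSet | Iterable[str],
    universe: Iterable[str] | int,
    label: str = "",
) -> EnrichmentResult:
    """One-sided Fisher exact test for over-representation of A in B.

    Both sets are intersected with the universe first; ``universe`` may be an
    explicit identifier collection or a bare size (in which case the sets are
    assumed already restricted). p = P(overlap >= observed) under
    hypergeometric sampling of |A| from a universe containing |B| successes.
    """
    a = _as_set(set_a)
    b = _as_set(set_b)
    if isinstance(universe, int):
        n_u = universe
    else:
        u = frozenset(universe)
        if not u:
            raise ParameterError("universe is empty")
        a &= u
        b &= u
        n_u = len(u)
    if n_u <= 0:
        raise ParameterError("universe is empty")
    if not a or not b:
        raise ParameterError("a gene set is empty after universe intersection")
    if len(a) > n_u or len(b) > n_u:
        raise ParameterError("set larger than universe")
    k = len(a & b)
    # survival function at k-1: P(X >= k), X ~ Hypergeom(N=n_u, K=|B|, n=|A|)
    p = float(hypergeom.sf(k - 1, n_u, len(b), len(a)))
    p = min(max(p, 0.0), 1.0)
    return EnrichmentResult(
        set_a_size=len(a),
        set_b_size=len(b),
        universe_size=n_u,
        overlap=k,
        fold_enrichment=fold_enrichment(k, len(a), len(b), n_u),
        p_value=p if p > 0 else np.nextafter(0, 1),
        label=label,
    )


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p-values must lie in [0,1]")
    return list(multipletests(p, method="fdr_bh")[1])


def celltype_annotation(
    modules: list[GeneModule],
    marker_sets: list[GeneSet],
    universe: Iterable[str],
    min_module_size: int = 50,
) -> tuple[pd.DataFrame, pd.Series]:
    """Module x cell-type matrix of BH-adjusted -log10 enrichment p-values.

    One Fisher test per (module, marker set); BH is applied across the whole
    matrix. Modules below the size floor are excluded up front. Returns the
    matrix and, per module, the arg-max cell type (the annotation call).
    Modules with no members in the universe are kept as all-NaN rows.
    """
    u = frozenset(universe)
    kept = [m for m in modules if len(m) >= min_module_size and m.label != "unassigned"]
    if not kept or not marker_sets:
        raise ParameterError("need at least one qualifying module and one marker set")
    rows = [m.label for m in kept]
    cols = [s.name for s in marker_sets]
    pmat = np.full((len(kept), len(cols)), np.nan)
    for i, mod in enumerate(kept):
        if not (mod.members & u):
            continue
        for j, mark in enumerate(marker_sets):
            try:
                pmat[i, j] = fisher_enrichment(mod.members, mark, u).p_value
            except ParameterError:
                pmat[i, j] = np.nan
    flat = pmat.ravel()
    ok = np.isfinite(flat)
    adj = np.full_like(flat, np.nan)
    if ok.any():
        adj[ok] = bh_adjust(flat[ok])
    adj_mat = adj.reshape(pmat.shape)
    neglog = pd.DataFrame(-np.log10(np.clip(adj_mat, 1e-300, 1.0)), index=rows, columns=cols)
    neglog[~np.isfinite(adj_mat)] = np.nan
    best = neglog.idxmax(axis=1)
    return neglog, best


def go_enrichment(
    deg_sets: list[GeneSet],
    term_sets: list[GeneSet],
    universe: Iterable[str],
    min_size: int = 100,
    max_size: int = 800,
) -> pd.DataFrame:
    """GO-style enrichment with a strict term-size window.

    Terms are intersected with the universe and kept only when
    min_size < |term| < max_size (strict on both ends). BH adjustment is
    applied within each DEG set separately. Returns a long-format table
    sortable by adjusted p.
    """
    u = frozenset(universe)
    terms = []
    for t in term_sets:
        members = t.members & u
        if min_size < len(members) < max_size:
            terms.append(GeneSet(t.name, members, description=t.description))
    if not terms:
        raise ParameterError("no term passes the size filter")
    records = []
    for dg in deg_sets:
        results = [fisher_enrichment(dg, t, u, label=t.name) for t in terms]
        adj = bh_adjust([r.p_value for r in results])
        for r, q in zip(results, adj):
            records.append(
                {
                    "deg_set": dg.name,
                    "term": r.label,
                    "overlap": r.overlap,
                    "deg_size": r.set_a_size,
                    "term_size": r.set_b_size,
                    "universe_size": r.universe_size,
                    "fold_enrichment": r.fold_enrichment,
                    "p_value": r.p_value,
                    "adjusted_p": q,
                }
            )
    return pd.DataFrame.from_records(records).sort_values(
        ["deg_set", "adjusted_p", "term"], ignore_index=True
    )


class MultiSetResult(EnrichmentResult):
    """Exact m-way intersection statistics (extends the 2-set result shape)."""

    def __init__(self, set_sizes, universe_size, overlap, fold_enrichment,
                 p_value, expected, log_p):
        super().__init__(
            set_a_size=set_sizes[0],
            set_b_size=set_sizes[1] if len(set_sizes) > 1 else 0,
            universe_size=universe_size,
            overlap=overlap,
            fold_enrichment=fold_enrichment,
            p_value=p_value,
        )
        self.set_sizes = list(set_sizes)
        self.expected = expected
        self.log_p = log_p


def _log_hypergeom_pmf(k: np.ndarray, n_total: int, n_success: int, n_draw: int) -> np.ndarray:
    k = np.asarray(k)
    with np.errstate(invalid="ignore"):
        val = (
            gammaln(n_success + 1) - gammaln(k + 1) - gammaln(n_success - k + 1)
            + gammaln(n_total - n_success + 1)
            - gammaln(n_draw - k + 1)
            - gammaln(n_total - n_success - (n_draw - k) + 1)
            - (gammaln(n_total + 1) - gammaln(n_draw + 1) - gammaln(n_total - n_draw + 1))
        )
    bad = (k < max(0, n_draw + n_success - n_total)) | (k > min(n_success, n_draw))
    val = np.where(bad, -np.inf, val)
    return val


def multiset_log_distribution(sizes: Sequence[int], universe_size: int) -> np.ndarray:
    """Exact log-PMF of the m-way intersection size under independent draws.

    Each set is a uniform sample of its size without replacement from the
    universe. The running intersection size is a Markov chain: conditional on
    the current size s, intersecting with the next set of size n is
    hypergeometric with s successes. Convolving the kernels yields the exact
    distribution; all arithmetic is in log space.
    """
    n_u = int(universe_size)
    if n_u <= 0:
        raise ParameterError("universe_size must be positive")
    sizes = [int(s) for s in sizes]
    if len(sizes) < 2:
        raise ParameterError("need at least two sets")
    if any(s < 0 or s > n_u for s in sizes):
        raise ParameterError("set sizes must lie in [0, universe size]")
    # running intersection of the first j sets; support shrinks as sets are
    # folded in (after set j it is min(sizes[:j]))
    logp = np.full(sizes[0] + 1, -np.inf)  # point mass at |first set|
    logp[sizes[0]] = 0.0
    for n_next in sizes[1:]:
        support = min(len(logp) - 1, n_next)
        new = np.full(support + 1, -np.inf)
        s_vals = np.nonzero(np.isfinite(logp))[0]
        k_vals = np.arange(support + 1)
        for s in s_vals:
            kernel = _log_hypergeom_pmf(k_vals, n_u, int(s), n_next)
            new = np.logaddexp(new, logp[s] + kernel)
        logp = new
    return logp


def multiset_intersection_test(
    sets: list[GeneSet | frozenset[str] | set[str]],
    universe_size: int | None = None,
    universe: Iterable[str] | None = None,
    observed: int | None = None,
) -> MultiSetResult:
    """Exact p for the observed m-way intersection being at least this large.

    FE = observed / expected with expected = U * prod(|S_i|/U). With m = 2
    this reduces to the one-sided Fisher exact test.
    """
    if universe is not None:
        u = frozenset(universe)
        members = [_as_set(s) & u for s in sets]
        n_u = len(u)
    else:
        members = [_as_set(s) for s in sets]
        if universe_size is None:
            raise ParameterError("provide universe or universe_size")
        n_u = int(universe_size)
    if len(members) < 2:
        raise ParameterError("need at least two sets")
    sizes = [len(m) for m in members]
    if observed is None:
        inter = members[0]
        for m in members[1:]:
            inter &= m
        observed = len(inter)
    if observed > min(sizes):
        raise ParameterError("observed intersection exceeds the smallest set")
    logp_dist = multiset_log_distribution(sizes, n_u)
    k = np.arange(len(logp_dist))
    tail = logp_dist[k >= observed]
    log_p = float(logsumexp(tail)) if tail.size else -np.inf
    log_p = min(log_p, 0.0)
    expected = n_u * float(np.prod([s / n_u for s in sizes]))
    fe = observed / expected if expected > 0 else np.inf if observed else 0.0
    return MultiSetResult(
        set_sizes=sizes,
        universe_size=n_u,
        overlap=int(observed),
        fold_enrichment=fe,
        p_value=float(np.exp(log_p)),
        expected=expected,
        log_p=log_p,
    )
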