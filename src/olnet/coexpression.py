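"""Weighted coexpression networks: correlation, soft threshold, TOM, modules.

The network is unsigned: adjacency a_ij = |r_ij|^beta. Module detection uses
average-linkage hierarchical clustering on 1 - TOM with a static branch cut;
modules smaller than the size floor are reassigned to "unassigned" (the
conventional grey label). Region-specific modules are merged by set union of
members into a core gene set.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datatypes import ExpressionMatrix, GeneModule
from .errors import InsufficientDataError, NumericalError, ParameterError

log = logging.getLogger(__name__)

__all__ = [
    "MODULE_COLORS",
    "SoftThresholdResult",
    "correlation_matrix",
    "pick_soft_threshold",
    "adjacency_from_correlation",
    "topological_overlap",
    "cluster_modules",
    "merge_modules",
    "residualize_covariates",
]

#: Fixed color-name pool for module labels, assigned by descending module size.
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
    "skyblue", "saddlebrown", "steelblue", "paleturquoise", "violet",
]

UNASSIGNED = "unassigned"


@dataclass
class SoftThresholdResult:
    """Scale-free fit per candidate power and the chosen exponent beta."""

    powers_tested: list[float]
    scale_free_fit: dict[float, float]
    chosen_power: float


def correlation_matrix(
    expr: ExpressionMatrix | pd.DataFrame,
    method: str = "pearson",
    min_pairwise: int = 10,
) -> pd.DataFrame:
    """Feature-feature Pearson correlation with pairwise-complete handling.

    Pairs with fewer than ``min_pairwise`` shared observations, and any pair
    involving a zero-variance feature, are returned as NaN (downstream they
    are treated as zero adjacency and excluded from module statistics).
    """
    if method != "pearson":
        raise ParameterError(f"unsupported correlation method {method!r}")
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if values.shape[1] < 3:
        raise InsufficientDataError(
            f"need >= 3 samples to correlate, got {values.shape[1]}"
        )
    x = values.T.astype(float)  # samples x features
    if x.isna().any().any():
        corr = x.corr(method="pearson", min_periods=min_pairwise)
    else:
        arr = x.to_numpy()
        sd = arr.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(arr, rowvar=False)
        c[~np.isfinite(c)] = np.nan
        corr = pd.DataFrame(c, index=values.index, columns=values.index)
        zero_var = sd == 0
        if zero_var.any():
            n_zero = int(zero_var.sum())
            log.warning("dropping %d zero-variance feature(s) from correlation", n_zero)
            corr.loc[zero_var, :] = np.nan
            corr.loc[:, zero_var] = np.nan
    np.fill_diagonal(corr.values, 1.0)
    zero_var_idx = values.index[values.std(axis=1, ddof=1) == 0]
    corr.loc[zero_var_idx, zero_var_idx.intersection(corr.columns)] = np.nan
    for f in zero_var_idx:
        corr.loc[f, f] = np.nan
    return corr


def adjacency_from_correlation(corr: pd.DataFrame, beta: float) -> pd.DataFrame:
    """Unsigned weighted adjacency |r|^beta with NaN pairs set to 0."""
    if beta <= 0:
        raise ParameterError("beta must be positive")
    adj = corr.abs() ** beta
    adj = adj.fillna(0.0)
    np.fill_diagonal(adj.values, 1.0)
    return adj


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10(frequency) on log10(mean connectivity) over bins.

    Sign follows the regression slope: a proper scale-free degree
    distribution has a negative slope, giving a positive signed fit.
    """
    k = k[np.isfinite(k) & (k > 0)]
    if k.size < 2 or np.allclose(k, k[0]):
        raise NumericalError("connectivity is constant; scale-free fit undefined")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freq = np.bincount(idx, minlength=n_bins).astype(float)
    kmean = np.array([k[idx == b].mean() if (idx == b).any() else np.nan for b in range(n_bins)])
    keep = (freq > 0) & np.isfinite(kmean) & (kmean > 0)
    if keep.sum() < 3:
        raise NumericalError("too few occupied connectivity bins for a fit")
    x = np.log10(kmean[keep])
    y = np.log10(freq[keep])
    if np.allclose(x, x[0]):
        raise NumericalError("degenerate connectivity bins")
    slope, _ = np.polyfit(x, y, 1)
    r = np.corrcoef(x, y)[0, 1]
    return float(-np.sign(slope) * r * r)


def pick_soft_threshold(
    corr: pd.DataFrame,
    powers: list[float] | None = None,
    target_r2: float = 0.8,
) -> SoftThresholdResult:
    """Choose the soft-thresholding exponent by the scale-free topology fit.

    Picks the smallest candidate power whose signed fit reaches ``target_r2``,
    falling back to the best-fitting power when none does.
    """
    if powers is None:
        powers = [1, 2, 3, 4, 5, 6, 8, 10, 12, 14, 16, 18, 20]
    powers = [float(p) for p in powers]
    if not powers:
        raise ParameterError("powers must be non-empty")
    fits: dict[float, float] = {}
    for p in powers:
        adj = corr.abs().fillna(0.0).to_numpy() ** p
        np.fill_diagonal(adj, 0.0)
        k = adj.sum(axis=1)
        fits[p] = _scale_free_fit(k)
    chosen = None
    for p in powers:
        if fits[p] >= target_r2:
            chosen = p
            break
    if chosen is None:
        chosen = max(powers, key=lambda p: fits[p])
    return SoftThresholdResult(powers_tested=powers, scale_free_fit=fits, chosen_power=chosen)


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of an unsigned weighted adjacency.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), with the
    diagonal set to 1. Entries stay in [0, 1] for adjacency entries in [0, 1].
    """
    a = adjacency.to_numpy(dtype=float).copy()
    if (a < -1e-12).any() or (a > 1 + 1e-12).any():
        raise ParameterError("adjacency entries must lie in [0,1]")
    a = np.clip(a, 0.0, 1.0)
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + a) / denom
    tom[~np.isfinite(tom)] = 0.0
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def cluster_modules(
    tom: pd.DataFrame,
    min_module_size: int = 10,
    cut_height: float = 0.995,
    region: str = "merged",
) -> list[GeneModule]:
    """Average-linkage clustering of 1 - TOM with a static branch cut.

    Clusters surviving the ``min_module_size`` floor become modules labelled
    from a fixed color list in order of descending size; everything else is
    collected into an "unassigned" module. Deterministic: ties in merge order
    follow scipy's stable ordering, and labels depend only on module sizes
    (size ties broken by smallest member id).
    """
    if min_module_size < 2:
        raise ParameterError("min_module_size must be >= 2")
    n = tom.shape[0]
    if min_module_size > n:
        raise ParameterError("min_module_size exceeds number of features")
    features = list(tom.index)
    dissim = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dissim, 0.0)
    dissim = (dissim + dissim.T) / 2.0
    z = linkage(squareform(dissim, checks=False), method="average")
    assignment = fcluster(z, t=cut_height, criterion="distance")

    groups: dict[int, list[str]] = {}
    for f, c in zip(features, assignment):
        groups.setdefault(int(c), []).append(f)
    surviving = [sorted(g) for g in groups.values() if len(g) >= min_module_size]
    surviving.sort(key=lambda g: (-len(g), g[0]))
    unassigned = sorted(
        f for g in groups.values() if len(g) < min_module_size for f in g
    )

    modules: list[GeneModule] = []
    for i, members in enumerate(surviving):
        label = MODULE_COLORS[i % len(MODULE_COLORS)]
        if i >= len(MODULE_COLORS):
            label = f"{label}{i // len(MODULE_COLORS) + 1}"
        modules.append(
            GeneModule(label=label, members=frozenset(members), region=region, universe_size=n)
        )
    if unassigned:
        modules.append(
            GeneModule(label=UNASSIGNED, members=frozenset(unassigned), region=region, universe_size=n)
        )
    return modules


def merge_modules(modules: list[GeneModule], label: str = "merged") -> GeneModule:
    """Union of member sets across region-specific modules (core gene set)."""
    if not modules:
        raise ParameterError("need at least one module to merge")
    members = frozenset().union(*(m.members for m in modules))
    return GeneModule(label=label, members=members, region="merged",
                      universe_size=max((m.universe_size or 0) for m in modules) or None)


def residualize_covariates(
    expr: ExpressionMatrix, covariate_columns: list[str]
) -> ExpressionMatrix:
    """Remove covariate effects by per-feature least squares before correlation.

    Categorical covariates are dummy-coded; numeric ones enter directly. Used
    for proteomics-style batch/age/sex correction.
    """
    meta = expr.sample_meta.loc[expr.sample_ids, covariate_columns]
    design = pd.get_dummies(meta, drop_first=True).astype(float)
    design.insert(0, "_intercept", 1.0)
    x = design.to_numpy()
    y = expr.values.to_numpy(dtype=float).T  # samples x features
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    values = pd.DataFrame(resid.T, index=expr.values.index, columns=expr.values.columns)
    return ExpressionMatrix(values, expr.sample_meta)
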