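"""Differential statistics: modular differential connectivity, protein-level
t-tests with Storey q-values, count filtering, and a voom/limma-style
moderated differential expression pipeline for RNA-seq contrasts.

Sign convention for MDC is case minus control: a negative value means loss
of intra-module correlation in the case (AD) group.
"""
from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess

from .datatypes import ExpressionMatrix, GeneModule, MDCResult, PerturbationSignature
from .enrichment import bh_adjust, multiset_intersection_test
from .errors import ParameterError

log = logging.getLogger(__name__)

__all__ = [
    "modular_differential_connectivity",
    "feature_ttest_qvalue",
    "storey_qvalues",
    "filter_low_counts",
    "log2_cpm",
    "voom_limma_deg",
    "signature_from_deg_table",
    "compare_signatures",
]

_Z_CLIP = 1.0 - 1e-6


def _mean_pairwise_zdiff(
    x: np.ndarray, case_idx: np.ndarray, control_idx: np.ndarray
) -> tuple[float, int, int]:
    """Mean over gene pairs of arctanh(r_case) - arctanh(r_control).

    ``x`` is genes x samples. Pairs involving a feature that is constant in
    either group are dropped; returns (mdc, n_pairs_used, n_pairs_dropped).
    """
    m = x.shape[0]
    iu = np.triu_indices(m, k=1)

    def _z(group: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        sub = x[:, group]
        sd = sub.std(axis=1, ddof=1)
        ok = sd > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(sub)
        r = np.clip(r, -_Z_CLIP, _Z_CLIP)
        return np.arctanh(r), ok

    z_case, ok_case = _z(case_idx)
    z_ctrl, ok_ctrl = _z(control_idx)
    ok = ok_case & ok_ctrl
    pair_ok = ok[iu[0]] & ok[iu[1]]
    diffs = (z_case - z_ctrl)[iu]
    used = int(pair_ok.sum())
    if used == 0:
        raise ParameterError("no usable gene pairs (constant features)")
    return float(diffs[pair_ok].mean()), used, int((~pair_ok).sum())


def modular_differential_connectivity(
    expr: ExpressionMatrix,
    module: GeneModule,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> MDCResult:
    """Mean difference in Fisher-z correlations (case minus control) with a
    permutation null.

    The null shuffles sample labels preserving group sizes; the empirical
    two-sided p is (1 + #{|MDC_perm| >= |MDC_obs|}) / (n_perm + 1). With the
    case and control groups literally identical the statistic is exactly 0.
    """
    case_ids = list(case_ids)
    control_ids = list(control_ids)
    if len(module) < 2:
        raise ParameterError("module must have >= 2 genes")
    if len(case_ids) < 4 or len(control_ids) < 4:
        raise ParameterError("each group needs >= 4 samples")
    same_group = list(case_ids) == list(control_ids)
    if not same_group and set(case_ids) & set(control_ids):
        raise ParameterError("case and control groups overlap")
    members = sorted(module.members)
    sub = expr.values.loc[[g for g in members if g in expr.values.index]]
    if sub.shape[0] < 2:
        raise ParameterError("fewer than 2 module genes present in matrix")

    if same_group:
        # identical groups: identical correlations by definition
        return MDCResult(
            module=module.label, n_case=len(case_ids), n_control=len(control_ids),
            mdc_value=0.0, n_permutations=0, permutation_p=1.0, seed=seed,
            n_pairs_used=sub.shape[0] * (sub.shape[0] - 1) // 2,
        )

    all_ids = case_ids + control_ids
    x = sub[all_ids].to_numpy(dtype=float)
    n_case = len(case_ids)
    idx_case = np.arange(n_case)
    idx_ctrl = np.arange(n_case, len(all_ids))
    mdc, used, dropped = _mean_pairwise_zdiff(x, idx_case, idx_ctrl)
    if dropped:
        log.info("MDC %s: dropped %d gene pairs with constant features", module.label, dropped)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(all_ids))
        stat, _, _ = _mean_pairwise_zdiff(x, perm[:n_case], perm[n_case:])
        if abs(stat) >= abs(mdc):
            count += 1
    p = (1 + count) / (n_perm + 1)
    return MDCResult(
        module=module.label, n_case=n_case, n_control=len(control_ids),
        mdc_value=mdc, n_permutations=n_perm, permutation_p=p, seed=seed,
        n_pairs_used=used, n_pairs_dropped=dropped,
    )


def storey_qvalues(p: np.ndarray, lambdas: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Storey q-values with smoother-based pi0 estimation.

    pi0(lambda) is computed on a lambda grid (0.05..0.95), smoothed with a
    cubic polynomial and read off at the largest lambda. Falls back to BH
    (pi0 = 1) when the estimate is unstable or there are < 100 features.
    """
    p = np.asarray(p, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    finite = np.isfinite(p)
    pf = p[finite]
    pi0 = 1.0
    if pf.size >= 100:
        pi0_l = np.array([(pf > lam).mean() / (1.0 - lam) for lam in lambdas])
        try:
            coef = np.polyfit(lambdas, pi0_l, 3)
            pi0 = float(np.polyval(coef, lambdas[-1]))
        except np.linalg.LinAlgError:
            pi0 = 1.0
        if not (0.0 < pi0 <= 1.0):
            pi0 = 1.0
    q = np.full_like(p, np.nan)
    m = pf.size
    order = np.argsort(pf)
    ranked = pf[order]
    qv = pi0 * ranked * m / np.arange(1, m + 1)
    qv = np.minimum.accumulate(qv[::-1])[::-1]
    qv = np.clip(qv, 0.0, 1.0)
    out = np.empty(m)
    out[order] = qv
    q[finite] = out
    return q, pi0


def feature_ttest_qvalue(
    expr: ExpressionMatrix,
    case_ids: Sequence[str],
    control_ids: Sequence[str],
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-feature two-sided two-sample t-test with Storey q-values.

    Classic equal-variance Student test by default (``equal_var=False``
    switches to Welch). Features with zero within-group variance in both
    groups get undefined (NaN) statistics.
    """
    case_ids, control_ids = list(case_ids), list(control_ids)
    if len(case_ids) < 2 or len(control_ids) < 2:
        raise ParameterError("each group needs >= 2 samples")
    a = expr.values[case_ids].to_numpy(dtype=float)
    b = expr.values[control_ids].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    degenerate = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    t = np.where(degenerate, np.nan, t)
    p = np.where(degenerate, np.nan, p)
    q, pi0 = storey_qvalues(p)
    return pd.DataFrame(
        {
            "feature": expr.values.index,
            "mean_case": a.mean(axis=1),
            "mean_control": b.mean(axis=1),
            "t": t,
            "p": p,
            "q": q,
            "pi0": pi0,
        }
    ).set_index("feature")


def filter_low_counts(
    counts: pd.DataFrame, min_count: int = 100, sample_fraction: float = 0.8
) -> tuple[pd.DataFrame, list[str]]:
    """Drop genes with < ``min_count`` counts in >= ``sample_fraction`` of samples.

    Returns the surviving matrix and the removed gene list.
    """
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise ParameterError("counts must be non-negative")
    n = counts.shape[1]
    n_low = (arr < min_count).sum(axis=1)
    removed_mask = n_low >= sample_fraction * n
    removed = list(counts.index[removed_mask])
    if removed:
        log.info("filter_low_counts: removed %d of %d genes", len(removed), counts.shape[0])
    return counts.loc[~removed_mask], removed


def log2_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """log2 counts-per-million with the voom offset:
    log2((count + 0.5) / (library_size + 1) * 1e6)."""
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    return np.log2((counts + 0.5) / (lib + 1.0) * 1e6)


def _squeeze_var(s2: np.ndarray, df_resid: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes variance shrinkage (method-of-moments prior fit).

    Models s^2 ~ s0^2 * F(df_resid, d0); estimates (d0, s0^2) from the
    moments of log s^2 and returns the posterior (moderated) variances.
    """
    ok = np.isfinite(s2) & (s2 > 0)
    z = np.log(s2[ok])
    e_z = z.mean()
    var_z = z.var(ddof=1) if z.size > 1 else 0.0
    tri = float(polygamma(1, df_resid / 2.0))
    excess = var_z - tri
    if excess <= 1e-8:
        d0 = np.inf
        log_s02 = e_z - (polygamma(0, df_resid / 2.0) - np.log(df_resid / 2.0))
        s02 = float(np.exp(log_s02))
        post = np.full_like(s2, s02)
        post[~ok] = np.nan
        return post, d0, s02

    # invert trigamma(d0/2) = excess by bisection
    lo, hi = 1e-3, 1e7
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if polygamma(1, mid / 2.0) > excess:
            lo = mid
        else:
            hi = mid
    d0 = float(np.sqrt(lo * hi))
    log_s02 = (
        e_z
        - (polygamma(0, df_resid / 2.0) - np.log(df_resid / 2.0))
        + (polygamma(0, d0 / 2.0) - np.log(d0 / 2.0))
    )
    s02 = float(np.exp(log_s02))
    post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
    post[~ok] = np.nan
    return post, d0, s02


def voom_limma_deg(
    counts: pd.DataFrame,
    group_labels: Sequence[str] | pd.Series,
    p_cut: float = 0.05,
    fdr_cut: float = 0.3,
    lowess_frac: float = 0.5,
    contrast: str = "KO_vs_WT",
) -> pd.DataFrame:
    """Precision-weighted log-CPM differential expression with a moderated t.

    The voom step: fit each gene's log2 CPM on the two-group design, lowess
    the sqrt residual SD against mean log2 count, and convert the trend into
    inverse-variance observation weights at each fitted count. The limma
    step: weighted least squares per gene, empirical-Bayes shrinkage of the
    residual variances, moderated t with df_resid + d0 degrees of freedom,
    BH FDR. The DEG signature requires p < ``p_cut`` AND FDR < ``fdr_cut``.

    ``group_labels`` must take exactly two values; the log2 fold change is
    second-level minus first-level in sorted label order, except that the
    conventional WT/control level is used as baseline when present.
    """
    labels = pd.Series(list(group_labels), index=counts.columns)
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ParameterError(f"need exactly two groups, got {levels}")
    for lv in levels:
        if (labels == lv).sum() < 2:
            raise ParameterError(f"group {lv!r} has < 2 samples")
    baselines = [lv for lv in levels if str(lv).upper() in ("WT", "CONTROL", "CTRL")]
    base = baselines[0] if baselines else levels[0]
    other = [lv for lv in levels if lv != base][0]

    y = log2_cpm(counts).to_numpy(dtype=float)  # genes x samples
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    n = y.shape[1]
    design = np.column_stack([np.ones(n), (labels == other).to_numpy(dtype=float)])
    q_params = design.shape[1]
    df_resid = n - q_params

    # unweighted fit for the mean-variance trend
    coef, *_ = np.linalg.lstsq(design, y.T, rcond=None)
    fitted = (design @ coef).T
    resid = y - fitted
    sigma = np.sqrt((resid**2).sum(axis=1) / df_resid)
    # voom trend on the count scale: mean log2 count per gene
    mean_log_count = y.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    order = np.argsort(mean_log_count)
    trend = lowess(
        np.sqrt(sigma)[order], mean_log_count[order], frac=lowess_frac, return_sorted=False
    )
    tx = mean_log_count[order]
    ty = trend
    # fitted log2 count for every observation -> predicted sqrt-SD -> weights
    fitted_log_count = fitted + (np.log2(lib + 1.0) - np.log2(1e6))[None, :]
    pred = np.interp(fitted_log_count, tx, ty)
    pred = np.clip(pred, 1e-4, None)
    w = pred**-4

    # weighted least squares per gene
    beta = np.empty(y.shape[0])
    s2 = np.empty(y.shape[0])
    se_unscaled = np.empty(y.shape[0])
    for g in range(y.shape[0]):
        wg = w[g]
        xtw = design.T * wg
        xtwx = xtw @ design
        xtwy = xtw @ y[g]
        try:
            b = np.linalg.solve(xtwx, xtwy)
            cov_unscaled = np.linalg.inv(xtwx)
        except np.linalg.LinAlgError:
            b = np.linalg.lstsq(xtwx, xtwy, rcond=None)[0]
            cov_unscaled = np.linalg.pinv(xtwx)
        r = y[g] - design @ b
        s2[g] = float((wg * r**2).sum() / df_resid)
        beta[g] = b[1]
        se_unscaled[g] = float(np.sqrt(cov_unscaled[1, 1]))

    post_s2, d0, _ = _squeeze_var(s2, df_resid)
    df_total = df_resid + (d0 if np.isfinite(d0) else 1e6)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_mod = beta / (np.sqrt(post_s2) * se_unscaled)
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    fdr = np.asarray(bh_adjust(np.nan_to_num(p, nan=1.0)))

    table = pd.DataFrame(
        {
            "gene": counts.index,
            "mean_log2_cpm": y.mean(axis=1),
            "log2_fc": beta,
            "t": t_mod,
            "p": p,
            "fdr": fdr,
        }
    )
    table["significant"] = (table["p"] < p_cut) & (table["fdr"] < fdr_cut)
    table["direction"] = np.where(table["log2_fc"] > 0, "up", "down")
    table.attrs["contrast"] = contrast
    table.attrs["thresholds"] = {"p": p_cut, "fdr": fdr_cut}
    table.attrs["prior_df"] = d0
    return table


def signature_from_deg_table(
    deg: pd.DataFrame, driver: str, region: str = ""
) -> PerturbationSignature:
    """Wrap the significant rows of a DEG table as a perturbation signature."""
    sig = deg.loc[deg["significant"], ["gene", "log2_fc", "p", "fdr", "direction"]].copy()
    return PerturbationSignature(driver=driver, region=region, deg_table=sig.reset_index(drop=True))


def compare_signatures(
    set_lists: list,
    compartment=None,
    universe: Iterable[str] | int | None = None,
):
    """m-way intersection of direction-stratified DEG sets with a compartment
    gene set: exact p and fold enrichment (delegates to the multi-set test)."""
    sets = list(set_lists) + ([compartment] if compartment is not None else [])
    if isinstance(universe, int) or universe is None:
        return multiset_intersection_test(sets, universe_size=universe)
    return multiset_intersection_test(sets, universe=universe)
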