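"""Metabolome-wide two-sample testing with Benjamini-Hochberg FDR.

Each feature is tested for a mean difference between two groups (Welch
t-test on log10 intensities by default), the resulting p values are
adjusted by the BH step-up procedure, and the Manhattan-plot data
(-log10 p per feature with the q-level significance line) are emitted.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import FeatureTable, group_map

logger = logging.getLogger("progmet")


def two_sample_t(table: FeatureTable, meta: pd.DataFrame, g1: str, g2: str,
                 on_log: bool = True, equal_var: bool = False) -> pd.DataFrame:
    """Per-feature two-sample t-test between groups ``g1`` and ``g2``.

    Expects replicate-averaged intensities (one run per sample).  Tests are
    Welch by default (``equal_var=True`` selects the pooled-variance
    variant) on log10 intensities unless ``on_log=False``.  Missing values
    are dropped pairwise; features with < 2 usable samples in either group
    are flagged untestable (p = NaN).  Features with zero variance in both
    groups and equal means get p = 1 and a warning flag.

    Returns a data frame with columns feature_id, mean_g1, mean_g2,
    t_stat, p_value, direction, untestable, zero_variance.
    """
    gm = group_map(meta)
    run_groups = np.array([gm.get(s) for s in table.sample_ids], dtype=object)
    for g in (g1, g2):
        if (run_groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has < 2 samples")
    x = table.intensities
    if on_log:
        with np.errstate(divide="ignore", invalid="ignore"):
            x = np.log10(x)
        x = np.where(np.isfinite(x), x, np.nan)
    a = x[:, run_groups == g1]
    b = x[:, run_groups == g2]

    import warnings as _warnings

    n_a = np.isfinite(a).sum(axis=1)
    n_b = np.isfinite(b).sum(axis=1)
    untestable = (n_a < 2) | (n_b < 2)
    with _warnings.catch_warnings(), np.errstate(invalid="ignore",
                                                 divide="ignore"):
        _warnings.simplefilter("ignore", RuntimeWarning)
        mean_a = np.nanmean(np.where(np.isfinite(a), a, np.nan), axis=1)
        mean_b = np.nanmean(np.where(np.isfinite(b), b, np.nan), axis=1)
        var_a = np.nanvar(np.where(np.isfinite(a), a, np.nan), axis=1, ddof=1)
        var_b = np.nanvar(np.where(np.isfinite(b), b, np.nan), axis=1, ddof=1)
        zero_var = (var_a == 0) & (var_b == 0)
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var,
                              nan_policy="omit")
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    # both-groups-constant, equal means: no evidence either way
    degenerate = zero_var & np.isclose(mean_a, mean_b)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    t[untestable] = np.nan
    p[untestable] = np.nan
    if degenerate.any():
        logger.warning("%d features constant in both groups (p set to 1)",
                       int(degenerate.sum()))

    return pd.DataFrame(
        {
            "feature_id": table.feature_id,
            "mz": table.mz,
            "time": table.rt,
            f"mean_{g1}": mean_a,
            f"mean_{g2}": mean_b,
            "t_stat": t,
            "p_value": p,
            "direction": np.sign(mean_b - mean_a),
            "untestable": untestable,
            "zero_variance": zero_var,
        }
    )


def bh_fdr(p_values, q: float = 0.2):
    """Benjamini-Hochberg step-up FDR at level ``q``.

    Returns ``(q_values, significant)``: monotone-adjusted q values and the
    boolean step-up significance set (largest rank i with
    p(i) <= (i/m) * q; everything at or below rank i is significant).
    NaN p values are never significant and get q = NaN.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    ok = np.isfinite(p)
    qvals = np.full(p.shape, np.nan)
    sig = np.zeros(p.shape, dtype=bool)
    if ok.any():
        reject, q_adj, _, _ = multipletests(p[ok], alpha=q, method="fdr_bh")
        qvals[ok] = q_adj
        sig[ok] = reject
    return qvals, sig


def univariate_table(table: FeatureTable, meta: pd.DataFrame, g1: str, g2: str,
                     q: float = 0.2, on_log: bool = True,
                     equal_var: bool = False) -> pd.DataFrame:
    """two_sample_t followed by bh_fdr; the full per-feature result table."""
    res = two_sample_t(table, meta, g1, g2, on_log=on_log, equal_var=equal_var)
    res["q_value"], res["significant_at_q"] = bh_fdr(res["p_value"].to_numpy(), q=q)
    logger.info("univariate %s vs %s: %d of %d significant at q=%g",
                g1, g2, int(res["significant_at_q"].sum()), len(res), q)
    return res


def manhattan_data(results: pd.DataFrame, q: float = 0.2):
    """Manhattan-plot data: (feature index, -log10 p, significant flag) and
    the horizontal line height (-log10 of the largest BH-significant p;
    None when nothing is significant)."""
    p = results["p_value"].to_numpy(dtype=float)
    if "significant_at_q" in results:
        sig = results["significant_at_q"].to_numpy(dtype=bool)
    else:
        _, sig = bh_fdr(p, q=q)
    with np.errstate(divide="ignore"):
        y = -np.log10(p)
    out = pd.DataFrame(
        {
            "feature_index": np.arange(len(results)),
            "feature_id": results["feature_id"].to_numpy(),
            "neg_log10_p": y,
            "significant": sig,
        }
    )
    line = None
    if sig.any():
        line = float(-np.log10(np.nanmax(p[sig])))
    return out, line
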