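"""Single-point response-factor quantification and group comparison.

A target ion is quantified absolutely against a reference material (e.g.
NIST SRM 1950 plasma): the response factor RF = reference concentration /
mean reference intensity converts each sample's replicate-averaged
intensity into a concentration (conc = RF x intensity).  Group differences
are assessed by one-way ANOVA with the Tukey HSD post test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

logger = logging.getLogger("progmet")


@dataclass
class CalibrationFactor:
    """Concentration-per-intensity conversion from a reference material."""

    response_factor: float      # nM per intensity unit
    ref_concentration: float    # nM
    ref_mean_intensity: float   # intensity units

    def __post_init__(self) -> None:
        if min(self.response_factor, self.ref_concentration,
               self.ref_mean_intensity) <= 0:
            raise ValueError("calibration quantities must be > 0")


@dataclass
class QuantResult:
    concentrations: pd.Series          # nM per sample
    group_summary: pd.DataFrame | None = None
    anova_f: float | None = None
    anova_p: float | None = None
    tukey: pd.DataFrame | None = None


def calibrate_rf(ref_intensities, ref_concentration: float,
                 blank_intensities=None, aggregate: str = "mean") -> CalibrationFactor:
    """Response factor from replicate reference-material intensities.

    RF = ref_concentration / aggregate(ref intensities), after optional
    blank subtraction (intensity - mean blank, floored at 0).
    """
    x = np.asarray(ref_intensities, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0 or np.any(x <= 0) or ref_concentration <= 0:
        raise ValueError("reference intensities and concentration must be > 0")
    if blank_intensities is not None:
        blank = float(np.nanmean(np.asarray(blank_intensities, dtype=float)))
        x = np.maximum(x - blank, 0.0)
        if np.all(x == 0):
            raise ValueError("blank subtraction removed the entire signal")
    agg = np.mean if aggregate == "mean" else np.median
    mean_int = float(agg(x))
    rf = ref_concentration / mean_int
    logger.info("calibrated RF = %.6g nM/intensity (ref %.4g nM / %.6g)",
                rf, ref_concentration, mean_int)
    return CalibrationFactor(rf, ref_concentration, mean_int)


def quantify_feature(sample_intensities: pd.DataFrame | dict,
                     cal: CalibrationFactor,
                     aggregate: str = "mean") -> QuantResult:
    """Per-sample concentration = RF x replicate-averaged intensity.

    ``sample_intensities`` maps sample_id -> iterable of replicate
    intensities (a dict or a wide DataFrame with samples as columns).
    Samples whose replicates are all missing get a missing concentration.
    """
    if isinstance(sample_intensities, pd.DataFrame):
        items = {c: sample_intensities[c].to_numpy(float)
                 for c in sample_intensities.columns}
    else:
        items = {k: np.asarray(v, dtype=float) for k, v in
                 sample_intensities.items()}
    agg = np.nanmean if aggregate == "mean" else np.nanmedian
    conc = {}
    for sid, reps in items.items():
        reps = reps[np.isfinite(reps)]
        conc[sid] = cal.response_factor * float(agg(reps)) if reps.size else np.nan
    return QuantResult(pd.Series(conc, name="concentration_nM"))


def anova_tukey(concentrations: pd.Series, groups: pd.Series | dict,
                alpha: float = 0.05) -> QuantResult:
    """One-way ANOVA across groups with the Tukey HSD post test
    (Tukey-Kramer for unequal group sizes)."""
    conc = pd.Series(concentrations).dropna()
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    g = groups.reindex(conc.index)
    by_group = {name: vals.to_numpy(float) for name, vals in conc.groupby(g)}
    if len(by_group) < 2:
        raise ValueError("need >= 2 groups")
    for name, vals in by_group.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has < 2 samples")
    arrays = list(by_group.values())
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        names = list(by_group)
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
        tukey_df = pd.DataFrame(
            {"group1": [p[0] for p in pairs], "group2": [p[1] for p in pairs],
             "meandiff": 0.0, "p_adj": 1.0, "reject": False}
        )
        summary = _group_summary(by_group)
        return QuantResult(conc, summary, 0.0, 1.0, tukey_df)
    f, p = stats.f_oneway(*arrays)
    res = pairwise_tukeyhsd(conc.to_numpy(float), g.to_numpy(object), alpha=alpha)
    tukey_df = pd.DataFrame(
        res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
    )[["group1", "group2", "meandiff", "p-adj", "reject"]]
    tukey_df = tukey_df.rename(columns={"p-adj": "p_adj"})
    # recover full-precision adjusted p values (summary table rounds)
    tukey_df["p_adj"] = res.pvalues
    logger.info("one-way ANOVA: F = %.4g, p = %.4g", f, p)
    return QuantResult(conc, _group_summary(by_group), float(f), float(p),
                       tukey_df)


def _group_summary(by_group: dict) -> pd.DataFrame:
    rows = [
        {"group": name, "n": len(v), "mean_nM": float(np.mean(v)),
         "sd_nM": float(np.std(v, ddof=1))}
        for name, v in by_group.items()
    ]
    return pd.DataFrame(rows)
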