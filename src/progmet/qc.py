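"""Feature quality control: detection filtering, replicate %CV, averaging.

The pipeline mirrors the conventional untargeted-metabolomics cascade:
keep features detected in (by default) 100% of analytical runs, compute the
per-feature technical coefficient of variation across replicate injections,
keep features with %CV <= 10, then collapse replicates to per-sample means
before any statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .containers import FeatureTable

logger = logging.getLogger("progmet")


@dataclass
class QcReport:
    n_input_features: int
    n_detected_all: int
    per_feature_cv: pd.Series  # %CV indexed by feature_id (NaN = not computable)
    n_pass_cv: int
    detection_fraction: float
    max_cv_pct: float
    sd_convention: str
    cv_aggregate: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature_id": self.per_feature_cv.index,
             "cv_pct": self.per_feature_cv.to_numpy()}
        )

    def summary(self) -> str:
        return (
            f"QC: {self.n_input_features} features in; "
            f"{self.n_detected_all} detected at fraction >= {self.detection_fraction}; "
            f"{self.n_pass_cv} with %CV <= {self.max_cv_pct} "
            f"({self.cv_aggregate} across samples, {self.sd_convention} SD)"
        )


def _detected(intens: np.ndarray) -> np.ndarray:
    """Detected = non-missing and strictly positive."""
    return np.isfinite(intens) & (intens > 0)


def detection_filter(table: FeatureTable, min_fraction: float = 1.0) -> FeatureTable:
    """Keep features detected in at least ``min_fraction`` of runs.

    A feature counts as detected in a run when its intensity is non-missing
    and > 0.  Feature order is preserved.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError(f"min_fraction must be in [0, 1], got {min_fraction}")
    frac = _detected(table.intensities).sum(axis=1) / table.n_runs
    keep = frac >= min_fraction
    out = table.subset_features(keep)
    logger.info("detection_filter(%.3g): %d -> %d features",
                min_fraction, table.n_features, out.n_features)
    return out


def replicate_cv(table: FeatureTable, sd_convention: str = "sample",
                 cv_aggregate: str = "median") -> pd.Series:
    """Per-feature technical %CV.

    Within each sample, CV = 100 * sd / mean over that sample's non-missing
    replicate intensities (samples with < 2 usable replicates are skipped
    for that feature).  Per feature the within-sample CVs are aggregated
    across samples by the median (xMSanalyzer convention) or the mean.
    ``sd_convention`` selects the n-1 ("sample", default) or n
    ("population") denominator.  Features with no usable sample get NaN.
    """
    if sd_convention not in ("sample", "population"):
        raise ValueError(f"unknown sd_convention {sd_convention!r}")
    if cv_aggregate not in ("median", "mean"):
        raise ValueError(f"unknown cv_aggregate {cv_aggregate!r}")
    ddof = 1 if sd_convention == "sample" else 0
    samples = table.samples
    per_sample = np.full((table.n_features, len(samples)), np.nan)
    for si, s in enumerate(samples):
        cols = table.sample_ids == s
        block = table.intensities[:, cols]
        finite = np.isfinite(block)
        n_use = finite.sum(axis=1)
        ok = n_use >= 2
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.nanmean(np.where(finite, block, np.nan), axis=1)
            sd = np.nanstd(np.where(finite, block, np.nan), axis=1, ddof=ddof)
            cv = 100.0 * sd / mean
        per_sample[ok, si] = cv[ok]
    with np.errstate(invalid="ignore"):
        agg = (np.nanmedian if cv_aggregate == "median" else np.nanmean)
        all_nan = np.all(np.isnan(per_sample), axis=1)
        out = np.full(table.n_features, np.nan)
        if not np.all(all_nan):
            out[~all_nan] = agg(per_sample[~all_nan], axis=1)
    return pd.Series(out, index=pd.Index(table.feature_id, name="feature_id"),
                     name="cv_pct")


def cv_filter(table: FeatureTable, max_cv_pct: float = 10.0,
              sd_convention: str = "sample",
              cv_aggregate: str = "median",
              detection_fraction: float = np.nan):
    """Keep features whose aggregated replicate %CV is <= ``max_cv_pct``.

    Returns (filtered table, QcReport).  Features whose CV cannot be
    computed (no sample with >= 2 usable replicates) are dropped.
    """
    cv = replicate_cv(table, sd_convention=sd_convention, cv_aggregate=cv_aggregate)
    keep = cv.to_numpy() <= max_cv_pct
    out = table.subset_features(keep)
    report = QcReport(
        n_input_features=table.n_features,
        n_detected_all=table.n_features,
        per_feature_cv=cv,
        n_pass_cv=out.n_features,
        detection_fraction=detection_fraction,
        max_cv_pct=max_cv_pct,
        sd_convention=sd_convention,
        cv_aggregate=cv_aggregate,
    )
    logger.info(report.summary())
    return out, report


def average_replicates(table: FeatureTable) -> FeatureTable:
    """Collapse technical replicates to one column per sample (mean of the
    non-missing replicate intensities; all-missing stays missing)."""
    samples = table.samples
    out = np.full((table.n_features, len(samples)), np.nan)
    groups = None if table.groups is None else np.empty(len(samples), dtype=object)
    for si, s in enumerate(samples):
        cols = table.sample_ids == s
        with np.errstate(invalid="ignore"):
            block = table.intensities[:, cols]
            any_finite = np.isfinite(block).any(axis=1)
            out[any_finite, si] = np.nanmean(block[any_finite], axis=1)
        if groups is not None:
            groups[si] = table.groups[np.flatnonzero(cols)[0]]
    return replace(
        table,
        intensities=out,
        sample_ids=np.array(samples, dtype=object),
        replicates=np.ones(len(samples), dtype=int),
        groups=groups,
    )
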