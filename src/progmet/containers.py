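"""Core data containers for the LC-MS feature-table pipeline.

An *m/z* feature is a detected ion characterised by its mass-to-charge
ratio, retention time and integrated ion intensity.  A :class:`FeatureTable`
holds the full cohort: one row per feature, one column per analytical run
(sample x technical replicate).  Missing intensities are ``NaN`` and are
distinct from a measured intensity of 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

GROUPS = ("control", "slow", "rapid")


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(ValueError):
    """A container violates one of its invariants."""


class ConfigurationError(ValueError):
    """A parameter set is internally inconsistent or infeasible."""


@dataclass
class FeatureTable:
    """Intensity matrix with feature and run annotations.

    Parameters
    ----------
    feature_id : array of str, shape (n_features,)
        Unique opaque feature identifiers.
    mz : array of float
        Mass-to-charge ratio (Da) per feature.
    rt : array of float
        Retention time (seconds) per feature.
    intensities : array of float, shape (n_features, n_runs)
        Nonnegative ion intensities; ``NaN`` marks a missing value.
    sample_ids : array of str, shape (n_runs,)
        Sample each run belongs to.
    replicates : array of int, shape (n_runs,)
        1-based technical-replicate index within the sample.
    groups : array of str or None
        Optional per-run group label (control / slow / rapid).
    """

    feature_id: np.ndarray
    mz: np.ndarray
    rt: np.ndarray
    intensities: np.ndarray
    sample_ids: np.ndarray
    replicates: np.ndarray
    groups: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.feature_id = np.asarray(self.feature_id, dtype=object)
        self.mz = np.asarray(self.mz, dtype=float)
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.replicates = np.asarray(self.replicates, dtype=int)
        if self.groups is not None:
            self.groups = np.asarray(self.groups, dtype=object)
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.feature_id)

    @property
    def n_runs(self) -> int:
        return self.intensities.shape[1]

    @property
    def samples(self) -> list[str]:
        """Unique sample ids in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(s, None)
        return list(seen)

    def validate(self) -> None:
        n, r = self.intensities.shape
        if not (len(self.feature_id) == len(self.mz) == len(self.rt) == n):
            raise ValidationError("feature annotation length mismatch")
        if not (len(self.sample_ids) == len(self.replicates) == r):
            raise ValidationError("run annotation length mismatch")
        if len(set(self.feature_id)) != n:
            dup = pd.Series(self.feature_id).value_counts()
            bad = dup[dup > 1].index.tolist()
            raise ValidationError(f"duplicate feature_id: {bad[:5]}")
        pairs = list(zip(self.mz.tolist(), self.rt.tolist()))
        if len(set(pairs)) != n:
            raise ValidationError("duplicate (mz, rt) pair")
        finite = np.isfinite(self.intensities)
        if np.any(self.intensities[finite] < 0):
            i = int(np.argwhere((self.intensities < 0) & finite)[0, 0])
            raise ValidationError(
                f"negative intensity in feature {self.feature_id[i]!r}"
            )
        key = list(zip(self.sample_ids.tolist(), self.replicates.tolist()))
        if len(set(key)) != r:
            raise ValidationError("duplicate (sample_id, replicate) run")
        if np.any(self.replicates < 1):
            raise ValidationError("replicate_index must be >= 1")
        if self.groups is not None and len(self.groups) != r:
            raise ValidationError("groups length mismatch")

    # ------------------------------------------------------------------
    def subset_features(self, mask: np.ndarray) -> "FeatureTable":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = mask
        else:
            idx = np.flatnonzero(mask)
        return replace(
            self,
            feature_id=self.feature_id[idx],
            mz=self.mz[idx],
            rt=self.rt[idx],
            intensities=self.intensities[idx, :],
        )

    def subset_runs(self, mask: np.ndarray) -> "FeatureTable":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return replace(
            self,
            intensities=self.intensities[:, idx],
            sample_ids=self.sample_ids[idx],
            replicates=self.replicates[idx],
            groups=None if self.groups is None else self.groups[idx],
        )

    def feature_index(self, feature_id: str) -> int:
        hits = np.flatnonzero(self.feature_id == feature_id)
        if len(hits) == 0:
            raise KeyError(f"unknown feature_id {feature_id!r}")
        return int(hits[0])

    def equals(self, other: "FeatureTable", rtol: float = 1e-12) -> bool:
        return (
            np.array_equal(self.feature_id, other.feature_id)
            and np.allclose(self.mz, other.mz, rtol=rtol)
            and np.allclose(self.rt, other.rt, rtol=rtol)
            and np.allclose(
                self.intensities, other.intensities, rtol=rtol, equal_nan=True
            )
            and np.array_equal(self.sample_ids, other.sample_ids)
            and np.array_equal(self.replicates, other.replicates)
        )

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{s}.{r}" for s, r in zip(self.sample_ids, self.replicates)]
        df = pd.DataFrame(self.intensities, columns=cols)
        df.insert(0, "time", self.rt)
        df.insert(0, "mz", self.mz)
        df.insert(0, "feature_id", self.feature_id)
        return df


def validate_sample_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata table (columns sample_id, group)."""
    for col in ("sample_id", "group"):
        if col not in meta.columns:
            raise FormatError(f"metadata missing column {col!r}")
    if meta["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in metadata")
    bad = set(meta["group"]) - set(GROUPS)
    if bad:
        raise ValidationError(f"unknown group labels: {sorted(bad)}")
    return meta


def group_map(meta: pd.DataFrame) -> dict[str, str]:
    validate_sample_meta(meta)
    return dict(zip(meta["sample_id"], meta["group"]))
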