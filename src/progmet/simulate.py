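"""Synthetic LC-MS cohort generator.

Emulates the statistical structure an untargeted serum-metabolomics feature
table is assumed to have: log-normal baseline ion intensities, a small set
of group-shifted effect features, block-correlated feature modules driven by
shared latent factors, multiplicative technical-replicate noise with a
configurable %CV, and optional missingness.  The generator returns the
planted ground truth so downstream stages can be scored for recovery.

Model
-----
Per feature *j* and sample *i* the true log10 intensity is

    log10 I_ij = mu_j + sigma_s * z_ij

with feature baselines mu_j ~ N(baseline_mean, baseline_sd^2) and
between-sample variation sigma_s = sample_sd.  Background features have
z_ij ~ N(0, 1) independent; members of module *k* share a latent factor,

    z_ij = sqrt(r) * f_ik + sqrt(1 - r) * eps_ij,

so any two members have Pearson correlation exactly ``within_module_r`` in
expectation.  Effect features gain ``effect_size * sample_sd`` on the log10
scale in the designated group.  Each technical replicate multiplies the
true intensity by exp(N(0, s_j^2)) with s_j set from that feature's target
%CV via CV^2 = exp(s^2) - 1; per-feature CVs are log-normal across features
(median ``replicate_cv_pct``, geometric SD ``cv_dispersion``) because real
features are heterogeneous in technical precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
import pandas as pd

from .containers import ConfigurationError, FeatureTable, GROUPS

logger = logging.getLogger("progmet")

_GROUP_PREFIX = {"control": "C", "slow": "S", "rapid": "R"}


@dataclass
class SynthConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study design the pipeline targets: 100 serum
    samples (20 controls, 41 slow and 39 rapid progressors) analysed in
    triplicate over an m/z scan range of 85-850, with 10 features shifted
    by 1.5 SD in the rapid group and 4 correlated modules of 25 features
    at within-module r = 0.7.
    """

    n_features: int = 1000
    n_per_group: dict = field(
        default_factory=lambda: {"control": 20, "slow": 41, "rapid": 39}
    )
    n_replicates: int = 3
    n_effect_features: int = 10
    effect_size: float = 1.5
    effect_group: str = "rapid"
    n_modules: int = 4
    module_size: int = 25
    within_module_r: float = 0.7
    between_module_r: float = 0.3
    replicate_cv_pct: float = 10.0
    cv_dispersion: float = 2.0
    missing_rate: float = 0.0
    mz_range: tuple = (85.0, 850.0)
    rt_range: tuple = (10.0, 600.0)
    baseline_mean: float = 5.0
    baseline_sd: float = 0.5
    sample_sd: float = 0.5
    seed: int = 17

    def validate(self) -> None:
        planted = self.n_effect_features + self.n_modules * self.module_size
        if planted > self.n_features:
            raise ConfigurationError(
                f"planted sets ({planted}) exceed n_features ({self.n_features})"
            )
        if not 0.0 <= self.within_module_r < 1.0:
            raise ConfigurationError("within_module_r must be in [0, 1)")
        if not 0.0 <= self.between_module_r < 1.0:
            raise ConfigurationError("between_module_r must be in [0, 1)")
        if self.replicate_cv_pct < 0:
            raise ConfigurationError("replicate_cv_pct must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if self.effect_group not in GROUPS:
            raise ConfigurationError(f"unknown effect_group {self.effect_group!r}")
        unknown = set(self.n_per_group) - set(GROUPS)
        if unknown:
            raise ConfigurationError(f"unknown groups {sorted(unknown)}")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")


@dataclass
class SynthTruth:
    """Planted ground truth: effect features, module labels, parameters."""

    effect_feature_ids: set
    module_labels: np.ndarray  # per-feature module id, 0 = background
    generator_params: SynthConfig

    def to_frame(self, feature_id: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": feature_id,
                "is_effect": [f in self.effect_feature_ids for f in feature_id],
                "module": self.module_labels,
            }
        )


def _cv_to_sigma(cv_pct: np.ndarray) -> np.ndarray:
    # CV of a log-normal multiplier exp(N(0, s^2)) is sqrt(exp(s^2) - 1)
    return np.sqrt(np.log1p((cv_pct / 100.0) ** 2))


def simulate_cohort(config: SynthConfig):
    """Generate a cohort: (FeatureTable, sample metadata, SynthTruth).

    Deterministic given the config (including its seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.n_features

    sample_ids, groups = [], []
    for g in GROUPS:
        for i in range(config.n_per_group.get(g, 0)):
            sample_ids.append(f"{_GROUP_PREFIX[g]}{i + 1:03d}")
            groups.append(g)
    n = len(sample_ids)
    meta = pd.DataFrame({"sample_id": sample_ids, "group": groups})

    mz = rng.uniform(*config.mz_range, size=m)
    rt = rng.uniform(*config.rt_range, size=m)
    feature_id = np.array([f"F{i + 1:05d}" for i in range(m)], dtype=object)

    # disjoint planted sets over a random permutation of features
    perm = rng.permutation(m)
    module_labels = np.zeros(m, dtype=int)
    pos = 0
    for k in range(1, config.n_modules + 1):
        module_labels[perm[pos:pos + config.module_size]] = k
        pos += config.module_size
    effect_idx = perm[pos:pos + config.n_effect_features]
    effect_ids = set(feature_id[effect_idx])

    # latent standard scores per (feature, sample); module factors share a
    # systemic driver so the eigengene network has structure to preserve
    z = rng.standard_normal((m, n))
    r = config.within_module_r
    rho = config.between_module_r
    shared = rng.standard_normal(n)
    for k in range(1, config.n_modules + 1):
        members = module_labels == k
        f_k = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * rng.standard_normal(n)
        z[members, :] = np.sqrt(r) * f_k + np.sqrt(1.0 - r) * z[members, :]

    mu = config.baseline_mean + config.baseline_sd * rng.standard_normal(m)
    log10_true = mu[:, None] + config.sample_sd * z
    in_effect_group = np.array([g == config.effect_group for g in groups])
    shift = config.effect_size * config.sample_sd
    log10_true[np.ix_(effect_idx, np.flatnonzero(in_effect_group))] += shift

    true_intensity = 10.0 ** log10_true

    # replicate-level multiplicative noise; heterogeneous per-feature %CV
    cv_j = config.replicate_cv_pct * np.exp(
        np.log(config.cv_dispersion) * rng.standard_normal(m)
    )
    sigma_j = _cv_to_sigma(cv_j)
    reps = config.n_replicates
    noise = np.exp(sigma_j[:, None, None] * rng.standard_normal((m, n, reps)))
    intens = (true_intensity[:, :, None] * noise).reshape(m, n * reps)

    if config.missing_rate > 0:
        miss = rng.random(intens.shape) < config.missing_rate
        intens = np.where(miss, np.nan, intens)

    run_samples = np.repeat(np.array(sample_ids, dtype=object), reps)
    run_reps = np.tile(np.arange(1, reps + 1), n)
    run_groups = np.repeat(np.array(groups, dtype=object), reps)

    table = FeatureTable(feature_id, mz, rt, intens, run_samples, run_reps,
                         groups=run_groups)
    truth = SynthTruth(effect_ids, module_labels, _dc_replace(config))
    logger.info(
        "simulated cohort: %d features x %d samples x %d replicates (seed=%d)",
        m, n, reps, config.seed,
    )
    return table, meta, truth


def inject_effect(table: FeatureTable, feature_ids, group: str,
                  effect_size: float, meta: pd.DataFrame | None = None) -> FeatureTable:
    """Shift designated features by ``effect_size`` feature-SDs (log10 scale)
    in the named group only; all other cells untouched.

    The per-feature SD is taken across all runs' log10 intensities before
    the shift.  Group membership comes from ``meta`` or, failing that, from
    the table's own per-run group labels.
    """
    if meta is not None:
        from .containers import group_map
        gm = group_map(meta)
        run_groups = np.array([gm.get(s) for s in table.sample_ids], dtype=object)
    elif table.groups is not None:
        run_groups = table.groups
    else:
        raise KeyError("no group labels available (pass meta)")
    if group not in GROUPS:
        raise KeyError(f"unknown group {group!r}")
    in_group = run_groups == group
    if not np.any(in_group):
        raise KeyError(f"group {group!r} has no runs in the table")

    rows = np.array([table.feature_index(f) for f in feature_ids], dtype=int)
    intens = table.intensities.copy()
    if len(rows) and effect_size != 0.0:
        with np.errstate(divide="ignore", invalid="ignore"):
            logI = np.log10(intens[rows, :])
        logI[~np.isfinite(logI)] = np.nan
        sd = np.nanstd(logI, axis=1, ddof=1)
        cols = np.flatnonzero(in_group)
        sub = logI[:, cols] + effect_size * sd[:, None]
        new = 10.0 ** sub
        old = intens[np.ix_(rows, cols)]
        bad = ~np.isfinite(sub)  # missing or zero intensity: leave as-is
        new[bad] = old[bad]
        intens[np.ix_(rows, cols)] = new
    from dataclasses import replace
    return replace(table, intensities=intens)
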