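import numpy as np
import pandas as pd
import pytest

from progmet import FeatureTable, SynthConfig, simulate_cohort


def make_table(intensities, sample_ids, replicates, groups=None,
               feature_ids=None, mz=None, rt=None) -> FeatureTable:
    """Build a small FeatureTable by hand for unit tests."""
    intensities = np.asarray(intensities, dtype=float)
    m = intensities.shape[0]
    if feature_ids is None:
        feature_ids = [f"F{i + 1}" for i in range(m)]
    if mz is None:
        mz = 100.0 + np.arange(m)
    if rt is None:
        rt = 60.0 + 5.0 * np.arange(m)
    return FeatureTable(
        np.array(feature_ids, dtype=object),
        np.asarray(mz, dtype=float),
        np.asarray(rt, dtype=float),
        intensities,
        np.array(sample_ids, dtype=object),
        np.asarray(replicates, dtype=int),
        groups=None if groups is None else np.array(groups, dtype=object),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-group synthetic cohort with planted structure."""
    cfg = SynthConfig(
        n_features=200,
        n_per_group={"control": 0, "slow": 40, "rapid": 40},
        n_effect_features=10,
        effect_size=1.5,
        n_modules=2,
        module_size=25,
        seed=17,
    )
    table, meta, truth = simulate_cohort(cfg)
    return table, meta, truth


@pytest.fixture
def toy_table():
    """3 features x (2 samples x 2 replicates), one missing cell."""
    intens = np.array(
        [
            [100.0, 110.0, 200.0, 210.0],
            [50.0, np.nan, 80.0, 90.0],
            [1.0, 2.0, 3.0, 4.0],
        ]
    )
    return make_table(intens, ["s1", "s1", "s2", "s2"], [1, 2, 1, 2])


@pytest.fixture
def meta_two_groups():
    return pd.DataFrame(
        {"sample_id": ["s1", "s2"], "group": ["slow", "rapid"]}
    )
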