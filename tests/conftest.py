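"""Shared fixtures: small synthetic fragments and prefab feature tables."""

import numpy as np
import pytest

from drowsyindex.band_features import (
    BAND_NAMES,
    CHANNELS,
    EegFragment,
    FeatureTable,
    build_feature_table,
    make_epoch_grid,
    preprocess,
)
from drowsyindex.synthetic_data import (
    CohortSpec,
    StageSpectrumProfile,
    generate_fragment,
)

N_EPOCHS = 238  # standard two-stage fragment
N_PER_STAGE = 119


def standard_labels(n_per_stage: int = N_PER_STAGE) -> np.ndarray:
    return np.array(["W"] * n_per_stage + ["S1"] * n_per_stage)


def table_from_values(values: np.ndarray, labels=None) -> FeatureTable:
    """Wrap an (epochs x 6 x 8) array as a FeatureTable."""
    if labels is None:
        labels = standard_labels(values.shape[0] // 2)
    return FeatureTable(values=values, stage_labels=labels)


def table_from_series(series: np.ndarray, labels=None) -> FeatureTable:
    """Feature table on which the delta-F3 / theta-F3 index reproduces
    ``series``: delta F3 carries the series, theta F3 is one."""
    n = len(series)
    values = np.zeros((n, len(CHANNELS), len(BAND_NAMES)))
    values[:, 0, BAND_NAMES.index("delta")] = series
    values[:, 0, BAND_NAMES.index("theta")] = 1.0
    return table_from_values(values, labels)


def series_probe_spec():
    """IndexSpec that reads the series back out of table_from_series."""
    from drowsyindex.ratio_indices import IndexSpec

    C = np.zeros((len(BAND_NAMES), len(CHANNELS)))
    K = np.zeros_like(C)
    C[BAND_NAMES.index("delta"), 0] = 1.0
    K[BAND_NAMES.index("theta"), 0] = 1.0
    return IndexSpec(C=C, K=K, name="probe")


def sinusoid_fragment(freq_hz: float, amplitude: float = 10.0,
                      total: float = 600.0, fs: float = 200.0) -> EegFragment:
    t = np.arange(int(total * fs)) / fs
    x = amplitude * np.sin(2 * np.pi * freq_hz * t)
    return EegFragment(samples=np.tile(x, (6, 1)), fs=fs,
                       stage_boundary=total / 2, total_duration=total,
                       subject_id="sine")


@pytest.fixture(scope="session")
def default_fragment() -> EegFragment:
    """One default-contrast synthetic fragment, preprocessed."""
    spec = CohortSpec(n_subjects=1, seed=7)
    return preprocess(generate_fragment(spec, 0))


@pytest.fixture(scope="session")
def default_feature_table(default_fragment) -> FeatureTable:
    grid = make_epoch_grid(default_fragment)
    return build_feature_table(default_fragment, grid)


@pytest.fixture(scope="session")
def small_cohort_tables() -> list:
    """Feature tables of a 4-subject default-contrast cohort."""
    spec = CohortSpec(n_subjects=4, seed=11)
    return [build_feature_table(preprocess(generate_fragment(spec, i)))
            for i in range(4)]


def no_contrast_cohort_spec(seed: int = 0, **kw) -> CohortSpec:
    """Cohort whose two stages share the same spectral profile."""
    w = StageSpectrumProfile({"delta": 4.0, "theta": 3.0, "alpha": 4.0,
                              "beta": 4.0, "gamma": 1.5}, stage="W")
    s1 = StageSpectrumProfile(dict(w.band_amplitudes), stage="S1")
    return CohortSpec(seed=seed, w_profile=w, s1_profile=s1, **kw)
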