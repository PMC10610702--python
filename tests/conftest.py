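"""Shared fixtures.

Small cohorts back the unit tests; the three protocol-scale cohorts
(20 + 20 subjects, 5 segments of 1000 samples, 126 FuzzyEn features) are
session-scoped because building one takes minutes.
"""

from __future__ import annotations

import numpy as np
import pytest

import eegentropy as ee
from eegentropy.features import build_features
from eegentropy.preprocess import preprocess_cohort
from eegentropy.simulate import default_profiles, generate_cohort

FUZZY_OPT = ee.EntropyConfig("FuzzyEn", m=1, r=0.15, r2=5)


def make_series(kind: str, n: int, seed: int) -> np.ndarray:
    """Seeded test series: white Gaussian noise or a stable AR(2) process."""
    rng = np.random.default_rng(seed)
    if kind == "gaussian":
        return rng.standard_normal(n)
    if kind == "ar":
        x = np.zeros(n + 50)
        e = rng.standard_normal(n + 50)
        for i in range(2, n + 50):
            x[i] = 1.2 * x[i - 1] - 0.5 * x[i - 2] + e[i]
        return x[50:]
    raise ValueError(kind)


@pytest.fixture(scope="session")
def tiny_cohort():
    """4+4 subjects, 16 s at 128 Hz, default NC/PD profiles."""
    return generate_cohort(4, default_profiles(), duration_s=16.0,
                           fs=128.0, seed=11)


@pytest.fixture(scope="session")
def tiny_segments(tiny_cohort):
    return preprocess_cohort(tiny_cohort, L_EEG=256, n_segments=5)


@pytest.fixture(scope="session")
def tiny_features(tiny_segments):
    return build_features(tiny_segments, FUZZY_OPT)


# ---- protocol-scale cohorts (acceptance tests) ----------------------------

_PROTOCOL_KW = dict(duration_s=300.0, fs=128.0)


@pytest.fixture(scope="session")
def null_features():
    """Identical-profile cohort: no class signal whatsoever."""
    nc = default_profiles()["NC"]
    records = generate_cohort(20, {"NC": nc, "PD": nc}, seed=501, **_PROTOCOL_KW)
    segments = preprocess_cohort(records, L_EEG=1000, n_segments=5)
    return build_features(segments, FUZZY_OPT)


@pytest.fixture(scope="session")
def effect_features():
    """Default NC/PD profiles: delta-power + delta-irregularity class gap."""
    records = generate_cohort(20, default_profiles(), seed=502, **_PROTOCOL_KW)
    segments = preprocess_cohort(records, L_EEG=1000, n_segments=5)
    return build_features(segments, FUZZY_OPT)


@pytest.fixture(scope="session")
def channel_effect_features():
    """Class effect restricted to channels P8 and F8."""
    records = generate_cohort(20, default_profiles(), seed=503,
                              effect_channels=["P8", "F8"], **_PROTOCOL_KW)
    segments = preprocess_cohort(records, L_EEG=1000, n_segments=5)
    return build_features(segments, FUZZY_OPT)
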