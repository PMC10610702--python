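"""Entropy estimators: closed-form identities, oracle equivalence, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegentropy.entropy import (
    EntropyConfig,
    attn_entropy,
    cosi_entropy,
    entropy_grid,
    fuzzy_entropy,
    perm_entropy,
    phase_entropy,
    samp_entropy,
    svd_entropy,
)
from eegentropy.exceptions import (
    DegenerateInputError,
    InvalidArgumentError,
    UndefinedEntropyWarning,
)

import reference as ref
from conftest import make_series

CONST = np.full(50, 3.7)
RAMP = np.arange(100, dtype=float)
ZIGZAG = np.tile([1.0, -1.0], 51)[:101]  # odd length: both m=2 patterns 50/50


# ---------------------------------------------------------------- identities
def test_constant_series_identities():
    assert svd_entropy(CONST, m=3, delay=1) == 0.0
    assert samp_entropy(CONST, m=2, r=0.2) == 0.0
    assert fuzzy_entropy(CONST, m=2, r=0.2, r2=2) == 0.0
    assert perm_entropy(CONST, m=3) == 0.0


def test_monotone_ramp_identities():
    assert perm_entropy(RAMP, m=4) == 0.0
    assert phase_entropy(RAMP, K=6) == 0.0


def test_period2_zigzag_identities():
    assert attn_entropy(ZIGZAG) == 0.0
    assert perm_entropy(ZIGZAG, m=2) == pytest.approx(1.0, abs=1e-12)


def test_cosi_binary_entropy_endpoints_are_zero():
    x = make_series("gaussian", 100, 0)
    assert cosi_entropy(x, m=2, r=1.0) == 0.0  # every pair within tolerance


def test_cosi_half_pairs_within_tolerance_gives_one():
    """r placed between the two middle order statistics of the enumerated
    angular distances makes B exactly 1/2, so the binary entropy is 1."""
    x = make_series("gaussian", 42, 3)  # 40 templates -> 780 pairs (even)
    dists = np.sort(ref.cosi_pair_distances_ref(x, 3))
    n = len(dists)
    assert n % 2 == 0
    r_half = 0.5 * (dists[n // 2 - 1] + dists[n // 2])
    assert dists[n // 2 - 1] < r_half < dists[n // 2]
    assert cosi_entropy(x, m=3, r=r_half) == pytest.approx(1.0, abs=1e-12)


def test_phase_equal_sector_mass_gives_one():
    """First-difference run of nine +1 steps and a double -1 step puts angle
    mass 3π in each of the K=2 sectors (verified by enumeration)."""
    d = np.array([1.0] * 10 + [-1.0, -1.0, 1.0])
    x = np.concatenate([[0.0], np.cumsum(d)])
    s = ref.phase_sector_sums_ref(x, 2)
    assert s[0] == pytest.approx(s[1], rel=1e-12)
    assert phase_entropy(x, K=2) == pytest.approx(1.0, abs=1e-9)


# ------------------------------------------------------- oracle equivalence
ORACLE_CASES = [
    ("SVDEn", lambda x: svd_entropy(x, m=4, delay=2),
     lambda x: ref.svd_entropy_ref(x, 4, 2)),
    ("PermEn", lambda x: perm_entropy(x, m=5, delay=1),
     lambda x: ref.perm_entropy_ref(x, 5, 1)),
    ("SampEn", lambda x: samp_entropy(x, m=2, r=0.25),
     lambda x: ref.samp_entropy_ref(x, 2, 0.25)),
    ("CoSiEn", lambda x: cosi_entropy(x, m=3, r=0.05),
     lambda x: ref.cosi_entropy_ref(x, 3, 0.05)),
    ("FuzzyEn", lambda x: fuzzy_entropy(x, m=1, r=0.15, r2=5),
     lambda x: ref.fuzzy_entropy_ref(x, 1, 0.15, 5)),
    ("FuzzyEn-m2", lambda x: fuzzy_entropy(x, m=2, r=0.3, r2=2),
     lambda x: ref.fuzzy_entropy_ref(x, 2, 0.3, 2)),
    ("PhaseEn", lambda x: phase_entropy(x, K=6),
     lambda x: ref.phase_entropy_ref(x, 6)),
    ("AttnEn", attn_entropy, ref.attn_entropy_ref),
]


@pytest.mark.parametrize("name,impl,oracle", ORACLE_CASES,
                         ids=[c[0] for c in ORACLE_CASES])
@pytest.mark.parametrize("kind", ["gaussian", "ar"])
def test_estimators_match_bruteforce_oracle(name, impl, oracle, kind):
    for seed in range(5):
        n = 150 + 83 * seed
        x = make_series(kind, n, seed)
        assert impl(x) == pytest.approx(oracle(x), abs=1e-9), (name, kind, seed)


# ------------------------------------------------------------- degeneracies
def test_svd_entropy_all_zero_input_raises():
    with pytest.raises(DegenerateInputError):
        svd_entropy(np.zeros(50), m=3)


def test_attn_entropy_monotone_input_raises():
    with pytest.raises(DegenerateInputError):
        attn_entropy(RAMP)


def test_cosi_entropy_zero_templates_raise():
    with pytest.raises(DegenerateInputError):
        cosi_entropy(np.zeros(30), m=2, r=0.1)


def test_samp_entropy_undefined_returns_nan_with_warning():
    with pytest.warns(UndefinedEntropyWarning):
        out = samp_entropy(RAMP, m=2, r=1e-12)
    assert math.isnan(out)


def test_phase_entropy_zero_angle_mass_is_zero_with_warning():
    # every second-difference angle exactly 0 (y = 0 at each point)
    flat = np.array([0.0, 1.0, 1.0, 1.0, 1.0])
    with pytest.warns(UndefinedEntropyWarning):
        assert phase_entropy(flat, K=4) == 0.0
    assert phase_entropy(make_series("gaussian", 100, 1), K=4) > 0


@pytest.mark.parametrize("fn,kwargs", [
    (svd_entropy, {"m": 1}),
    (samp_entropy, {"r": -0.1}),
    (cosi_entropy, {"r": 0.0}),
    (fuzzy_entropy, {"r2": 0}),
    (phase_entropy, {"K": 1}),
])
def test_invalid_hyperparameters_raise(fn, kwargs):
    x = make_series("gaussian", 100, 0)
    with pytest.raises(InvalidArgumentError):
        fn(x, **kwargs)


# ---------------------------------------------------------------- invariants
@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.integers(0, 10_000), st.integers(40, 300))
def test_normalized_measures_bounded_in_unit_interval(seed, n):
    x = make_series("gaussian", n, seed)
    for val in (
        svd_entropy(x, m=3), perm_entropy(x, m=3),
        cosi_entropy(x, m=2, r=0.1), phase_entropy(x, K=5),
    ):
        assert 0.0 <= val <= 1.0


def test_fuzzy_scale_invariance():
    x = make_series("gaussian", 300, 11)
    # r2=1: tolerance proportional to std makes the measure scale-free
    assert fuzzy_entropy(3.7 * x, m=2, r=0.2, r2=1) == pytest.approx(
        fuzzy_entropy(x, m=2, r=0.2, r2=1), abs=1e-9)
    # r2!=1: invariance only after rescaling to unit std before the call
    u = x / x.std()
    assert fuzzy_entropy(5.0 * u / (5.0 * u).std(), m=1, r=0.15, r2=5) == \
        pytest.approx(fuzzy_entropy(u, m=1, r=0.15, r2=5), abs=1e-9)


@pytest.mark.parametrize("fn,kwargs", [
    (fuzzy_entropy, {"m": 1, "r": 0.15, "r2": 5}),
    (samp_entropy, {"m": 2, "r": 0.25}),
    (perm_entropy, {"m": 5}),
])
def test_noise_is_more_complex_than_a_pure_tone(fn, kwargs):
    t = np.arange(1000) / 128.0
    noise_vals, sine_vals = [], []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        noise_vals.append(fn(rng.standard_normal(1000), **kwargs))
        sine_vals.append(fn(np.sin(2 * np.pi * 10 * t + rng.uniform(0, 2 * np.pi)),
                            **kwargs))
    assert np.mean(noise_vals) > np.mean(sine_vals)


def test_fuzzy_entropy_nondecreasing_in_additive_noise():
    t = np.arange(1000) / 128.0
    sigmas = [0.0, 0.1, 0.3, 1.0]
    means = []
    for sigma in sigmas:
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            x = np.sin(2 * np.pi * 10 * t) + sigma * rng.standard_normal(1000)
            vals.append(fuzzy_entropy(x, m=1, r=0.15, r2=5))
        means.append(np.mean(vals))
    assert all(b >= a for a, b in zip(means, means[1:]))


# --------------------------------------------------------------------- grids
def test_grid_sizes_match_parameter_ranges():
    assert len(entropy_grid("SVDEn")) == 9
    assert len(entropy_grid("PermEn")) == 9
    assert len(entropy_grid("SampEn")) == 30
    assert len(entropy_grid("CoSiEn")) == 20
    assert len(entropy_grid("FuzzyEn")) == 100
    assert len(entropy_grid("PhaseEn")) == 9
    assert len(entropy_grid("AttnEn")) == 1


def test_fuzzy_grid_tolerance_lattice():
    rs = sorted({c.r for c in entropy_grid("FuzzyEn")})
    assert rs == [pytest.approx(0.05 * i) for i in range(1, 11)]
    assert any(c.r == 0.15 and c.m == 1 and c.r2 == 5
               for c in entropy_grid("FuzzyEn"))


def test_phase_grid_sectors():
    assert [c.K for c in entropy_grid("PhaseEn")] == list(range(2, 11))


def test_unknown_method_raises():
    with pytest.raises(InvalidArgumentError):
        entropy_grid("BubbleEn")
    with pytest.raises(InvalidArgumentError):
        EntropyConfig("NopeEn")


def test_config_label_round_trip():
    cfg = EntropyConfig("FuzzyEn", m=1, r=0.15, r2=5)
    assert cfg.label() == "FuzzyEn|m=1,r=0.15,r2=5"
    assert EntropyConfig.from_label(cfg.label()) == cfg
    attn = EntropyConfig("AttnEn")
    assert EntropyConfig.from_label(attn.label()) == attn
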