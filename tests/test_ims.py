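"""The TOF transfer function: conversions, derivation from timing, estimation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import toffee as tf
from toffee._errors import EstimationError, IndexRangeError, UnderdeterminedError


@pytest.mark.parametrize(
    "i, alpha, beta, gamma, expected",
    [
        (4, 1.0, 0.0, 0, 16.0),
        (0, 2.0, 1.0, 1, 9.0),
    ],
)
def test_mz_from_index_examples(i, alpha, beta, gamma, expected):
    assert tf.mz_from_index(i, tf.IMSParams(alpha, beta, gamma)) == expected


@pytest.mark.parametrize(
    "mz, alpha, beta, gamma, expected",
    [
        (16.0, 1.0, 0.0, 0, 4),
        (16.4, 1.0, 0.0, 0, 4),  # sqrt(16.4) ~ 4.0497 rounds down
    ],
)
def test_index_from_mz_examples(mz, alpha, beta, gamma, expected):
    assert tf.index_from_mz(mz, tf.IMSParams(alpha, beta, gamma)) == expected


def test_negative_radical_raises():
    with pytest.raises(IndexRangeError):
        tf.mz_from_index(-10, tf.IMSParams(1.0, 0.0, 0))


@pytest.mark.parametrize(
    "timing, expected",
    [
        (dict(delta_t=1, t0_prime=2.5, U=0.5, d=1), (1.0, -0.5, 3)),
        (dict(delta_t=1, t0_prime=0.0, U=0.5, d=1), (1.0, 0.0, 0)),
    ],
)
def test_ims_from_instrument_examples(timing, expected):
    p = tf.ims_from_instrument(tf.InstrumentTiming(**timing))
    alpha, beta, gamma = expected
    assert p.alpha == pytest.approx(alpha, abs=0, rel=1e-15)
    assert p.beta == pytest.approx(beta, abs=1e-15)
    assert p.gamma == gamma


def test_instrument_physics_oracle_single_index():
    """Index 1000 of a given timing must reproduce the squared arrival-time
    physics: m/z = [sqrt(2U)/d * (delta_t*i + t0')]**2 evaluated independently."""
    timing = tf.InstrumentTiming(delta_t=1e-9, t0_prime=5e-9, U=2e4, d=1.0)
    i = 1000
    t_arrival = timing.delta_t * i + timing.t0_prime
    expected = (math.sqrt(2 * timing.U) / timing.d * t_arrival) ** 2
    got = tf.mz_from_index(i, tf.ims_from_instrument(timing))
    assert got == pytest.approx(expected, rel=1e-12)


def test_instrument_physics_oracle_random_timings():
    rng = np.random.default_rng(42)
    for _ in range(100):
        timing = tf.InstrumentTiming(
            delta_t=10 ** rng.uniform(-10, -8),
            t0_prime=rng.uniform(0, 1e-6),
            U=10 ** rng.uniform(3, 5),
            d=rng.uniform(0.5, 2.0),
        )
        p = tf.ims_from_instrument(timing)
        i = rng.integers(100, 10**6)
        s = math.sqrt(2 * timing.U) / timing.d
        expected = (s * timing.delta_t * (i + timing.t0_prime / timing.delta_t)) ** 2
        assert tf.mz_from_index(int(i), p) == pytest.approx(expected, rel=1e-12)


@settings(derandomize=True, max_examples=200)
@given(
    alpha=st.floats(1e-6, 1e-2),
    beta_frac=st.floats(-0.49, 0.5),
    gamma=st.integers(-100, 100),
    i=st.integers(0, 2**22),
)
def test_index_mz_round_trip_property(alpha, beta_frac, gamma, i):
    """index_from_mz inverts mz_from_index exactly on every lattice point."""
    p = tf.IMSParams(alpha, beta_frac * alpha, gamma)
    if i + gamma < 1:  # radical base must stay on the positive branch
        return
    assert tf.index_from_mz(tf.mz_from_index(i, p), p) == i


def test_mz_monotone_in_index():
    p = tf.IMSParams(3.3e-4, 1e-5, 7)
    i = np.arange(1000, 5000)
    mz = tf.mz_from_index(i, p)
    assert np.all(np.diff(mz) > 0)


# --- per-scan estimation -----------------------------------------------------


def test_estimate_recovers_small_lattice():
    gen = tf.IMSParams(0.002, 0.3, 0)
    mz = np.square(gen.alpha * np.array([100, 101, 105]) + gen.beta)
    est = tf.estimate_scan_ims(mz)
    assert est.max_residual_ppm <= 1e-6
    fit = np.square(est.params.alpha * (est.indices + est.params.gamma) + est.params.beta)
    np.testing.assert_allclose(fit, mz, rtol=1e-12)


def test_estimate_two_values_underdetermined():
    with pytest.raises(UnderdeterminedError):
        tf.estimate_scan_ims([100.0, 101.0])


def test_estimate_identifiability_noiseless():
    """On noiseless lattice data alpha is recovered to 1e-9 relative and the
    combined offset to 1e-9 absolute in sqrt(Da)."""
    rng = np.random.default_rng(7)
    for _ in range(25):
        alpha = 10 ** rng.uniform(-4.3, -3.3)
        beta = rng.uniform(-0.5, 0.5) * alpha
        idx = np.unique(rng.integers(10**5, 5 * 10**5, size=80))
        # guarantee a run of adjacent indices (profile data is contiguous)
        idx = np.unique(np.concatenate([idx, idx[0] + np.arange(8)]))
        mz = np.square(alpha * idx + beta)
        est = tf.estimate_scan_ims(mz)
        assert abs(est.params.alpha - alpha) / alpha <= 1e-9
        assert abs(est.params.offset - beta) <= 1e-9
        np.testing.assert_array_equal(est.indices, idx)
        assert est.max_residual_ppm <= 1e-6


def test_estimate_with_ppm_noise():
    rng = np.random.default_rng(13)
    alpha, beta = 7.5e-5, 1e-5
    idx = np.unique(rng.integers(2 * 10**5, 4 * 10**5, size=300))
    idx = np.unique(np.concatenate([idx, idx[0] + np.arange(10)]))
    mz = np.square(alpha * idx + beta)
    mz = mz * (1 + rng.uniform(-0.1e-6, 0.1e-6, size=mz.size))
    est = tf.estimate_scan_ims(np.sort(mz))
    assert est.max_residual_ppm <= 0.2


def test_estimate_sparse_scan_gcd_path():
    """Scans whose index gaps are all large multiples still resolve the lattice."""
    rng = np.random.default_rng(3)
    alpha, beta = 7.5e-5, 0.0
    idx = np.unique(np.cumsum(rng.integers(2, 40, size=60)) + 10**5)
    mz = np.square(alpha * idx + beta)
    est = tf.estimate_scan_ims(mz)
    assert abs(est.params.alpha - alpha) / alpha <= 1e-9
    assert est.max_residual_ppm <= 1e-6


def test_estimate_failure_reports_residual():
    rng = np.random.default_rng(5)
    mz = np.sort(rng.uniform(400, 500, size=40))  # not on any lattice
    with pytest.raises(EstimationError) as exc:
        tf.estimate_scan_ims(mz, tolerance_ppm=1e-4)
    assert exc.value.max_residual_ppm > 1e-4


def test_estimate_seeded_tiny_scans_exact():
    """1- and 2-point scans placed via a warm start reproduce m/z exactly."""
    alpha, beta = 7.5e-5, 1e-5
    seed = tf.IMSParams(alpha, beta, 0)
    idx = np.array([250000, 250017])
    mz = np.square(alpha * idx + beta)
    est2 = tf.estimate_scan_ims(mz, seed_params=seed)
    assert est2.max_residual_ppm <= 1e-6
    est1 = tf.estimate_scan_ims(mz[:1], seed_params=seed)
    assert est1.max_residual_ppm <= 1e-6
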