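"""The analytic peak model: evaluation, fitting, amplitude-as-area, outliers."""

import numpy as np
import pytest
import scipy.integrate

import toffee as tf
from toffee._errors import DegenerateInputError
from toffee.requant import (
    CohortRecord,
    FragmentRaster,
    PeakModelParams,
    eval_model,
    fit_peak,
    flag_outliers,
)
from toffee.synthetic import generate_peak_raster

SQRT2PI = np.sqrt(2 * np.pi)


@pytest.fixture(scope="module")
def true_params():
    return PeakModelParams(
        sigma_t=0.02, sigma_m=2.0, t0=100.0,
        m0=np.array([50.0, 52.0, 48.5]),
        a=np.array([5000.0, 3000.0, 1500.0]),
        c=np.array([20.0, 0.0, 0.0]),
    )


@pytest.fixture(scope="module")
def grid():
    t = 100.0 * np.exp(np.linspace(-0.08, 0.08, 25))
    m = np.arange(35.0, 66.0)
    return t, m


def test_apex_value(true_params):
    p = true_params
    val = eval_model(p, p.t0, p.m0[1], 1)
    assert val == pytest.approx(p.a[1] / (p.t0 * p.sigma_t * SQRT2PI), rel=1e-12)


def test_ms1_noise_floor_at_large_t(true_params):
    p = true_params
    val = eval_model(p, 1e9, p.m0[0], 0, is_ms1=True)
    assert val == pytest.approx(p.c[0], rel=1e-6)


def test_symmetry_in_m(true_params):
    p = true_params
    for delta in (0.5, 1.7, 3.0):
        lhs = eval_model(p, 95.0, p.m0[2] + delta, 2)
        rhs = eval_model(p, 95.0, p.m0[2] - delta, 2)
        assert lhs == pytest.approx(rhs, rel=1e-12)


def test_t_nonpositive_rejected(true_params):
    with pytest.raises(ValueError):
        eval_model(true_params, 0.0, 50.0, 0)


def test_amplitude_is_elution_area(true_params):
    """Integrating the t-profile at m = m0 (c = 0) over t > 0 yields a_j:
    the fitted amplitude is the peak area, justifying its use as the
    re-quantified intensity."""
    p = PeakModelParams(sigma_t=0.05, sigma_m=2.0, t0=120.0,
                        m0=np.array([10.0]), a=np.array([700.0]))
    val, err = scipy.integrate.quad(
        lambda t: eval_model(p, t, 10.0, 0), 1e-3, 1e5, limit=200,
        points=[60.0, 120.0, 240.0],
    )
    assert val == pytest.approx(700.0, rel=1e-6)


def test_noiseless_fit_is_exact(true_params, grid):
    t, m = grid
    raster = generate_peak_raster(true_params, t, m, noise_sigma=0.0,
                                  is_ms1=[True, False, False])
    fit = fit_peak(raster)
    assert fit.residual <= 1e-6 * float((raster.I**2).sum())


def test_parameter_recovery_with_noise(true_params, grid):
    t, m = grid
    apex = eval_model(true_params, true_params.t0, true_params.m0[0], 0)
    raster = generate_peak_raster(true_params, t, m, noise_sigma=0.01 * apex,
                                  seed=1, is_ms1=[True, False, False])
    fit = fit_peak(raster)
    p = fit.params
    assert p.t0 == pytest.approx(true_params.t0, rel=0.02)
    assert p.sigma_t == pytest.approx(true_params.sigma_t, rel=0.05)
    assert p.sigma_m == pytest.approx(true_params.sigma_m, rel=0.05)
    np.testing.assert_allclose(fit.requant_intensity, true_params.a, rtol=0.02)


def test_recovery_from_perturbed_init(true_params, grid):
    t, m = grid
    raster = generate_peak_raster(true_params, t, m, noise_sigma=0.0,
                                  is_ms1=[True, False, False])
    init = PeakModelParams(
        sigma_t=0.03, sigma_m=3.0, t0=103.0,
        m0=true_params.m0 + 1.0, a=true_params.a * 1.4, c=np.array([0.0, 0, 0]),
    )
    fit = fit_peak(raster, init=init)
    assert fit.params.t0 == pytest.approx(true_params.t0, rel=1e-4)


def test_recovery_degrades_monotonically(true_params, grid):
    t, m = grid
    apex = eval_model(true_params, true_params.t0, true_params.m0[0], 0)
    errs = []
    for sigma in (0.005, 0.05, 0.2):
        raster = generate_peak_raster(true_params, t, m, noise_sigma=sigma * apex,
                                      seed=4, is_ms1=[True, False, False])
        fit = fit_peak(raster)
        errs.append(float(np.max(np.abs(fit.requant_intensity - true_params.a) / true_params.a)))
    assert errs[0] < errs[1] < errs[2]


def test_shift_equivariance(true_params, grid):
    t, m = grid
    raster = generate_peak_raster(true_params, t, m, noise_sigma=0.0,
                                  is_ms1=[True, False, False])
    shifted = FragmentRaster(t=raster.t, m=raster.m + 37.0, I=raster.I,
                             is_ms1=raster.is_ms1)
    f0 = fit_peak(raster)
    f1 = fit_peak(shifted)
    np.testing.assert_allclose(f1.params.m0, f0.params.m0 + 37.0, atol=1e-6)
    assert f1.params.t0 == pytest.approx(f0.params.t0, rel=1e-9)
    np.testing.assert_allclose(f1.params.a, f0.params.a, rtol=1e-7)


def test_all_zero_raster_rejected(grid):
    t, m = grid
    raster = FragmentRaster(t=t, m=m, I=np.zeros((2, t.size, m.size)),
                            is_ms1=[False, False])
    with pytest.raises(DegenerateInputError):
        fit_peak(raster)


# --- cohort outlier flagging -------------------------------------------------


def _record(sigma_t=0.02, sigma_m=2.0, t0=100.0, dm=0.0):
    p = PeakModelParams(sigma_t=sigma_t, sigma_m=sigma_m, t0=t0,
                        m0=np.array([50.0 + dm]), a=np.array([100.0]))
    return CohortRecord(params=p, expected_rt=100.0, library_m0=np.array([50.0]))


def test_gross_outlier_flagged():
    cohort = [
        _record(sigma_t=0.02 + 0.0002 * k) for k in range(15)
    ] + [_record(sigma_t=0.2)]
    flags = flag_outliers(cohort)
    assert flags[-1]
    assert not flags[:-1].any()


def test_identical_cohort_unflagged():
    flags = flag_outliers([_record() for _ in range(12)])
    assert not flags.any()


def test_small_cohort_rejected():
    with pytest.raises(ValueError):
        flag_outliers([_record() for _ in range(9)])


def test_planted_outliers_detected():
    """5% of entries planted at 6 robust sigma in one feature each: at least
    90% of them flagged, at most 5% of the inliers flagged."""
    rng = np.random.default_rng(8)
    n = 400
    sig_t = rng.normal(0.02, 0.002, n)
    sig_m = rng.normal(2.0, 0.15, n)
    t0 = rng.normal(100.0, 1.0, n)
    dm = rng.normal(0.0, 0.3, n)
    outlier = np.zeros(n, dtype=bool)
    planted = rng.choice(n, size=n // 20, replace=False)
    outlier[planted] = True
    for k, idx in enumerate(planted):
        feature = k % 4
        if feature == 0:
            sig_t[idx] = 0.02 + 6 * 0.002
        elif feature == 1:
            sig_m[idx] = 2.0 + 6 * 0.15
        elif feature == 2:
            t0[idx] = 100.0 + 6 * 1.0
        else:
            dm[idx] = 6 * 0.3
    cohort = [
        _record(sigma_t=max(sig_t[i], 1e-4), sigma_m=max(sig_m[i], 0.1),
                t0=t0[i], dm=dm[i])
        for i in range(n)
    ]
    flags = flag_outliers(cohort)
    sensitivity = flags[outlier].mean()
    false_rate = flags[~outlier].mean()
    assert sensitivity >= 0.90
    assert false_rate <= 0.05
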