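"""Analytic 2D peak model and re-quantification.

Chromatographic elution is approximately log-normal in retention time and the
TOF detector spreads each ion approximately normally in m/z index space, so a
peptide's signal for fragment ``j`` on the (t, m) grid is modelled as

    F_j = (1/t) * a_j/(sigma_t*sqrt(2*pi))
          * exp[-(log t - log t0)^2/(2 sigma_t^2) - (m - m0_j)^2/(2 sigma_m^2)]
          + C_j,

with a t-independent chemical-noise ridge C_j = c_j*exp[-(m-m0_j)^2/(2 sigma_m^2)]
included for MS1 traces only.  The retention-time apex ``t0`` and spreads are
shared across fragments (co-eluting fragments must peak together) while the
index centre ``m0_j`` is free per fragment to absorb calibration offsets.
Because the t-factor is a log-normal density scaled by ``a_j``, the fitted
amplitude is the area of the elution peak and serves directly as the
re-quantified intensity.

Fitting minimises the summed squared residual over all fragments with a
bounded trust-region least-squares solver; the cohort-level outlier flagger
marks fits whose shape or location parameters are extreme relative to their
cohort (robust z-score on median/MAD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from ._errors import DegenerateInputError, FitFailureError

__all__ = [
    "PeakModelParams",
    "FragmentRaster",
    "FitResult",
    "CohortRecord",
    "eval_model",
    "fit_peak",
    "flag_outliers",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass
class PeakModelParams:
    """Parameters of the shared-apex multi-fragment peak model."""

    sigma_t: float  # spread in log-retention-time
    sigma_m: float  # spread in index space
    t0: float  # retention-time apex, s
    m0: np.ndarray  # index centre per fragment
    a: np.ndarray  # amplitude (elution-peak area) per fragment
    c: np.ndarray | None = None  # chemical-noise amplitude per fragment (MS1 only)

    def __post_init__(self):
        self.m0 = np.atleast_1d(np.asarray(self.m0, dtype=np.float64))
        self.a = np.atleast_1d(np.asarray(self.a, dtype=np.float64))
        if self.c is None:
            self.c = np.zeros_like(self.a)
        self.c = np.atleast_1d(np.asarray(self.c, dtype=np.float64))
        if not (self.sigma_t > 0 and self.sigma_m > 0 and self.t0 > 0):
            raise ValueError("sigma_t, sigma_m and t0 must be positive")
        if not (len(self.m0) == len(self.a) == len(self.c)):
            raise ValueError("m0, a and c must have one entry per fragment")

    @property
    def n_fragments(self) -> int:
        return len(self.m0)


@dataclass
class FragmentRaster:
    """Observed intensities on a shared (t, m) grid, one matrix per fragment."""

    t: np.ndarray  # scan retention times, s (strictly positive)
    m: np.ndarray  # index coordinates
    I: np.ndarray  # (n_fragments, len(t), len(m))
    is_ms1: np.ndarray  # bool per fragment

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=np.float64)
        self.m = np.asarray(self.m, dtype=np.float64)
        self.I = np.asarray(self.I, dtype=np.float64)
        self.is_ms1 = np.atleast_1d(np.asarray(self.is_ms1, dtype=bool))
        if np.any(self.t <= 0):
            raise ValueError("retention times must be positive (log t must exist)")
        if self.I.shape != (len(self.is_ms1), len(self.t), len(self.m)):
            raise ValueError("I must have shape (n_fragments, len(t), len(m))")

    @property
    def n_fragments(self) -> int:
        return self.I.shape[0]


def eval_model(params: PeakModelParams, t, m, j: int, is_ms1: bool = False):
    """Model intensity F_j on the grid spanned by ``t`` (rows) and ``m`` (cols).

    Scalars in, scalar out; vectors in, (len(t), len(m)) matrix out.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=np.float64))
    m_arr = np.atleast_1d(np.asarray(m, dtype=np.float64))
    if np.any(t_arr <= 0):
        raise ValueError("t must be positive")
    gm = np.exp(-((m_arr - params.m0[j]) ** 2) / (2.0 * params.sigma_m**2))
    lt = (
        params.a[j]
        / (t_arr * params.sigma_t * _SQRT2PI)
        * np.exp(-((np.log(t_arr) - np.log(params.t0)) ** 2) / (2.0 * params.sigma_t**2))
    )
    out = np.outer(lt, gm)
    if is_ms1:
        out = out + params.c[j] * gm[None, :]
    if np.isscalar(t) and np.isscalar(m):
        return float(out[0, 0])
    return out


def _model_stack(params: PeakModelParams, raster: FragmentRaster) -> np.ndarray:
    return np.stack(
        [
            eval_model(params, raster.t, raster.m, j, is_ms1=bool(raster.is_ms1[j]))
            for j in range(raster.n_fragments)
        ]
    )


@dataclass
class FitResult:
    params: PeakModelParams
    residual: float  # achieved sum of squared residuals G
    requant_intensity: np.ndarray = field(default=None)  # fitted a_j per fragment

    def __post_init__(self):
        if self.requant_intensity is None:
            self.requant_intensity = self.params.a.copy()


def _initial_params(raster: FragmentRaster) -> PeakModelParams:
    """Deterministic moment-based initialisation (no random restarts)."""
    J = raster.n_fragments
    xic = raster.I.sum(axis=(0, 2))  # summed-fragment chromatogram
    t0 = float(raster.t[int(np.argmax(xic))])
    w = np.clip(xic, 0, None)
    if w.sum() > 0:
        logt = np.log(raster.t)
        mu = float(np.average(logt, weights=w))
        sigma_t = float(np.sqrt(np.average((logt - mu) ** 2, weights=w)))
    else:
        sigma_t = 0.05
    sigma_t = float(np.clip(sigma_t, 1e-3, 2.0))

    m0 = np.empty(J)
    sig_m = []
    a = np.empty(J)
    for j in range(J):
        wj = raster.I[j]
        tot = wj.sum()
        prof = wj.sum(axis=0)
        if tot > 0:
            m0[j] = float(np.average(raster.m, weights=prof))
            sig_m.append(
                float(np.sqrt(np.average((raster.m - m0[j]) ** 2, weights=prof)))
            )
        else:
            m0[j] = float(raster.m.mean())
        apex = float(wj.max())
        a[j] = apex * sigma_t * t0 * _SQRT2PI
    sigma_m = float(np.clip(np.mean(sig_m) if sig_m else 1.0, 0.1, 50.0))
    return PeakModelParams(
        sigma_t=sigma_t, sigma_m=sigma_m, t0=t0, m0=m0, a=a, c=np.zeros(J)
    )


def fit_peak(
    raster: FragmentRaster,
    init: PeakModelParams | None = None,
    max_nfev: int = 2000,
) -> FitResult:
    """Fit the shared-apex peak model to a multi-fragment raster.

    Bounded trust-region nonlinear least squares over
    (sigma_t, sigma_m, t0, m0_j, a_j, c_j); ``c_j`` is only optimised for MS1
    fragments and pinned at 0 otherwise.

    Raises
    ------
    DegenerateInputError
        All-zero raster.
    FitFailureError
        Solver did not converge within the evaluation budget; the exception
        carries the best parameters and residual reached.
    """
    if raster.I.size == 0 or not np.any(raster.I):
        raise DegenerateInputError("all-zero raster: nothing to fit")
    J = raster.n_fragments
    n_params = 3 + 2 * J + int(raster.is_ms1.sum())
    if raster.I.size < n_params:
        raise DegenerateInputError(
            f"raster has {raster.I.size} points but the model has {n_params} parameters"
        )
    p0 = init if init is not None else _initial_params(raster)
    ms1_idx = np.where(raster.is_ms1)[0]

    def pack(p: PeakModelParams) -> np.ndarray:
        return np.concatenate(
            [[p.sigma_t, p.sigma_m, p.t0], p.m0, p.a, p.c[ms1_idx]]
        )

    def unpack(x: np.ndarray) -> PeakModelParams:
        c = np.zeros(J)
        c[ms1_idx] = x[3 + 2 * J :]
        return PeakModelParams(
            sigma_t=x[0], sigma_m=x[1], t0=x[2],
            m0=x[3 : 3 + J], a=x[3 + J : 3 + 2 * J], c=c,
        )

    m_lo, m_hi = float(raster.m.min()), float(raster.m.max())
    t_lo, t_hi = float(raster.t.min()), float(raster.t.max())
    lower = np.concatenate(
        [[1e-3, 0.1, t_lo], np.full(J, m_lo - 5.0), np.zeros(J), np.zeros(len(ms1_idx))]
    )
    upper = np.concatenate(
        [[2.0, 50.0, t_hi], np.full(J, m_hi + 5.0), np.full(J, np.inf),
         np.full(len(ms1_idx), np.inf)]
    )
    x0 = np.clip(pack(p0), lower, upper)

    def residuals(x):
        return (_model_stack(unpack(x), raster) - raster.I).ravel()

    res = scipy.optimize.least_squares(
        residuals, x0, bounds=(lower, upper), method="trf", max_nfev=max_nfev
    )
    params = unpack(res.x)
    g = float(np.sum(res.fun**2))
    if not res.success:
        raise FitFailureError(
            f"peak fit did not converge within {max_nfev} evaluations "
            f"(status {res.status}); residual {g:.4g}",
            params=params,
            residual=g,
        )
    return FitResult(params=params, residual=g)


@dataclass
class CohortRecord:
    """One fitted peptide with the library expectations it is judged against."""

    params: PeakModelParams
    expected_rt: float
    library_m0: np.ndarray  # expected index centre per fragment

    def features(self) -> np.ndarray:
        dm = np.max(np.abs(self.params.m0 - np.asarray(self.library_m0, dtype=float)))
        return np.array(
            [
                self.params.sigma_t,
                self.params.sigma_m,
                abs(self.params.t0 - self.expected_rt),
                dm,
            ]
        )


def flag_outliers(cohort: list[CohortRecord], threshold: float = 5.0) -> np.ndarray:
    """Flag fits whose shape/location features deviate from the cohort.

    A robust z-score (median / scaled MAD) is computed per feature; an entry is
    flagged when any feature exceeds ``threshold``.  Peak spreads and locations
    are systematic properties of an acquisition, so extreme fits are the
    re-quantification pipeline's false-positive candidates.
    """
    if len(cohort) < 10:
        raise ValueError(f"cohort must have at least 10 entries, got {len(cohort)}")
    feats = np.stack([r.features() for r in cohort])
    med = np.median(feats, axis=0)
    mad = np.median(np.abs(feats - med), axis=0) * 1.4826
    dev = np.abs(feats - med)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(dev == 0, 0.0, dev / np.where(mad == 0, np.nan, mad))
    z = np.where(np.isnan(z) & (dev > 0), np.inf, np.nan_to_num(z, nan=0.0))
    return np.any(z > threshold, axis=1)
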