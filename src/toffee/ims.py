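"""Time-of-flight intrinsic mass spacing (IMS): the m/z <-> integer index layer.

A TOF analyser samples ion arrival times at a fixed interval, and arrival time
is proportional to sqrt(m/z).  Every observed m/z therefore sits on a lattice

    m/z(i) = [alpha * (i + gamma) + beta]**2

indexed by the integer sample number ``i``.  ``alpha`` is the lattice spacing
in sqrt(Da) per sample, ``gamma`` an integer index offset, and ``beta`` the
sub-sample remainder of the arrival-time offset.  This module converts between
the two spaces, derives the coefficients from instrument timing, and estimates
them per scan from observed m/z vectors — the operation that makes integer
storage lossless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._errors import EstimationError, IndexRangeError, UnderdeterminedError

__all__ = [
    "IMSParams",
    "InstrumentTiming",
    "ScanEstimate",
    "mz_from_index",
    "index_from_mz",
    "ims_from_instrument",
    "estimate_scan_ims",
    "round_half_away",
]


def round_half_away(x):
    """Round to nearest integer with halves going away from zero.

    Stated explicitly (rather than relying on numpy's banker's rounding)
    because half-sample ties do occur with perturbed inputs.
    """
    x = np.asarray(x)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass(frozen=True)
class IMSParams:
    """Intrinsic mass spacing coefficients of one scan (or window median).

    Attributes
    ----------
    alpha : float
        Lattice spacing, sqrt(Da) per index step; strictly positive.
    beta : float
        Sub-sample offset, sqrt(Da).
    gamma : int
        Integer index offset (a storage convention; only ``alpha`` and the
        combined offset ``alpha * gamma + beta`` are physically identified).
    """

    alpha: float
    beta: float
    gamma: int = 0

    def __post_init__(self):
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.gamma != int(self.gamma):
            raise ValueError(f"gamma must be an integer, got {self.gamma}")

    @property
    def offset(self) -> float:
        """The identified combined offset alpha*gamma + beta, sqrt(Da)."""
        return self.alpha * self.gamma + self.beta


@dataclass(frozen=True)
class InstrumentTiming:
    """Sensor timing and flight geometry of a TOF analyser.

    ``delta_t`` is the sampling interval (s), ``t0_prime`` the arrival-time
    offset (s), ``U`` the accelerating potential and ``d`` the flight distance
    (any consistent unit system).
    """

    delta_t: float
    t0_prime: float
    U: float
    d: float

    def __post_init__(self):
        if not (self.delta_t > 0 and self.U > 0 and self.d > 0):
            raise ValueError("delta_t, U and d must all be positive")

    @property
    def slope(self) -> float:
        """sqrt(2U)/d: sqrt(m/z) per second of arrival time."""
        return math.sqrt(2.0 * self.U) / self.d


def mz_from_index(i, params: IMSParams):
    """m/z of integer index ``i``: [alpha*(i + gamma) + beta]**2.

    Raises
    ------
    IndexRangeError
        If the radical base alpha*(i+gamma)+beta is not positive, i.e. the
        index is outside the physical (monotonic) branch.
    """
    i = np.asarray(i, dtype=np.float64)
    root = params.alpha * (i + params.gamma) + params.beta
    if np.any(root <= 0):
        raise IndexRangeError(
            "index outside physical range: alpha*(i+gamma)+beta must be positive"
        )
    out = np.square(root)
    return float(out) if out.ndim == 0 else out


def index_from_mz(mz, params: IMSParams):
    """Nearest integer index of m/z value(s): round((sqrt(mz) - beta)/alpha - gamma).

    Exact inverse of :func:`mz_from_index` on lattice points.  Rounding is
    half-away-from-zero.
    """
    mz = np.asarray(mz, dtype=np.float64)
    if np.any(mz <= 0):
        raise ValueError("m/z must be positive")
    i = round_half_away((np.sqrt(mz) - params.beta) / params.alpha - params.gamma)
    out = i.astype(np.int64)
    return int(out) if out.ndim == 0 else out


def ims_from_instrument(timing: InstrumentTiming) -> IMSParams:
    """Derive IMS coefficients from instrument timing.

    alpha = delta_t * sqrt(2U) / d, gamma = ceil(t0'/delta_t),
    beta = alpha * (t0'/delta_t - gamma); beta lies in (-alpha, 0].
    """
    alpha = timing.delta_t * timing.slope
    gamma = int(math.ceil(timing.t0_prime / timing.delta_t))
    beta = alpha * (timing.t0_prime / timing.delta_t - gamma)
    return IMSParams(alpha=alpha, beta=beta, gamma=gamma)


@dataclass(frozen=True)
class ScanEstimate:
    """Result of per-scan IMS estimation."""

    params: IMSParams
    indices: np.ndarray
    max_residual_ppm: float

    def __iter__(self):  # allow tuple unpacking
        yield self.params
        yield self.indices
        yield self.max_residual_ppm


def _canonicalise(alpha: float, offset: float, rel_idx: np.ndarray):
    """Fold the combined offset into absolute indices: gamma=0, |beta| <= alpha/2."""
    shift = int(round_half_away(offset / alpha))
    beta = offset - alpha * shift
    indices = rel_idx.astype(np.int64) + shift
    return IMSParams(alpha=alpha, beta=beta, gamma=0), indices


def _pairwise_gcd(d: np.ndarray, eps: float, noise: float, floor: float) -> float:
    """Fold a nearest-integer Euclid GCD over exact-to-rounding reals.

    Each step replaces (a, b) by (b, |a - round(a/b)*b|); the fold accumulates
    over all values.  Suited to data whose values are integer multiples of the
    answer up to float rounding (``eps``).  The error of each remainder is the
    input error amplified by the quotient, so it is tracked explicitly: a
    remainder within its own error of zero means "exact multiple, keep the
    divisor", and before a quotient would push the divisor's error past useful
    precision the divisor — itself a multiple of the true spacing — is
    re-tightened by least squares against every difference consistent with it.
    Without that, one large quotient amplifies rounding error enough that
    later exact multiples look like fresh remainders and the fold collapses.
    Off-lattice data drive the divisor towards ``floor`` regardless; the
    caller's residual and resolution checks reject the resulting spurious
    fine lattice.
    """
    g = float(d.min())
    err = eps
    for x in np.sort(d):
        a, ea = float(x), eps
        b, eb = g, err
        for _ in range(256):
            q = float(round_half_away(a / b))
            er = ea + q * eb + eps
            if er > 1e-7 * b and eb > eps:
                b, u = _refine_spacing(d, b, noise, u0=max(eb / b, noise / b))
                eb = max(u * b, eps)
                q = float(round_half_away(a / b))
                er = ea + q * eb + eps
            rem = abs(a - q * b)
            if rem <= 10.0 * er + 5.0 * noise:
                break
            a, ea, b, eb = b, eb, rem, er
            if b <= floor:
                return b
        g, err = b, eb
    return g


def _approx_gcd(d: np.ndarray, g0: float, noise: float, rel_floor: float = 0.1,
                max_iter: int = 64, floor: float = 0.0) -> float:
    """Approximate common divisor of noisy positive reals.

    The sqrt(m/z) differences of a lattice scan are integer multiples of the
    spacing.  Starting from the seed ``g0``, any residue after rounding each
    difference to its nearest multiple that exceeds ``rel_floor`` of the
    candidate is itself a smaller multiple of the spacing and becomes the new
    candidate (a set-wide Euclid step).  On a true lattice the residues
    collapse to noise scale once the candidate reaches the spacing, so the
    iteration terminates there; on off-lattice data the residue-to-candidate
    ratio stays uniform at every scale, the candidate shrinks without bound
    (a small enough spacing fits anything), and the iteration ends at
    ``floor`` — the caller treats that as "no representable lattice".
    """
    g = g0
    u = None
    for _ in range(max_iter):
        if g <= floor:
            return g
        g, u = _refine_spacing(d, g, noise, u0=u)
        k_all = round_half_away(d / g)
        res = np.abs(d - k_all * g)
        big = res > np.maximum(rel_floor * g, 5.0 * noise)
        if not np.any(big):
            return g
        # the smallest significant residue is the next candidate, but every
        # residue carries the candidate's error amplified by the multiple
        # that produced it; sharpen the new candidate on the residue spectrum
        # (where its own multiples are small) under that inflated noise
        noise_res = noise + float(k_all.max()) * g * u
        g = float(res[big].min())
        g, u = _refine_spacing(res[big], g, noise_res, u0=noise_res / g)
    return g


def _refine_spacing(d: np.ndarray, g: float, noise: float,
                    u0: float | None = None,
                    max_iter: int = 64) -> tuple[float, float]:
    """Refine a spacing candidate by least squares over its multiples.

    A difference spanning K multiples only has an unambiguous integer
    assignment when K times the relative uncertainty of the candidate is
    below 1/4, so refinement proceeds progressively: start with the small
    multiples, update the uncertainty from the fit residuals, and let the
    admissible multiple range grow until it stops changing.  The inclusion
    window scales with ``noise`` and the current uncertainty so that genuine
    sub-multiple residues — real lattice structure finer than the candidate —
    are never absorbed as if they were noise.  ``u0`` is the candidate's
    initial relative uncertainty; returns the refined spacing together with
    its final uncertainty so callers can chain refinements.
    """
    u = max(noise / g, 1e-15) if u0 is None else max(u0, noise / g, 1e-15)
    prev_ok = None
    for _ in range(max_iter):
        k = round_half_away(d / g)
        res = np.abs(d - k * g)
        k_cap = max(0.25 / u, 1.0)
        ok = (k >= 1) & (k <= k_cap) & (res <= 3.0 * u * g * k + 5.0 * noise)
        if not np.any(ok):
            return g, u
        g_new = float(np.dot(d[ok], k[ok]) / np.dot(k[ok], k[ok]))
        u_new = max(
            float(np.sqrt(np.sum(res[ok] ** 2) / np.sum((k[ok] * g) ** 2))), 1e-15
        )
        stable = prev_ok is not None and np.array_equal(ok, prev_ok)
        converged = abs(g_new - g) <= 1e-15 * g
        g, u = g_new, u_new
        if stable and converged:
            break
        prev_ok = ok
    return g, u


def _lstsq_line(idx: np.ndarray, r: np.ndarray):
    """Least-squares r = alpha*idx + b via centred normal equations (stable)."""
    im = idx.mean()
    rm = r.mean()
    ic = idx - im
    denom = float(np.dot(ic, ic))
    alpha = float(np.dot(ic, r - rm)) / denom
    b = rm - alpha * im
    return alpha, b


def _fit_lattice(mz: np.ndarray, r: np.ndarray, alpha: float, idx: np.ndarray,
                 max_iter: int) -> tuple[IMSParams, np.ndarray, float]:
    """Alternate least squares on (alpha, offset) with index reassignment."""
    b = float(r[0] - alpha * idx[0])
    for _ in range(max_iter):
        alpha, b = _lstsq_line(idx, r)
        new_idx = round_half_away((r - b) / alpha)
        if np.array_equal(new_idx, idx):
            break
        idx = new_idx
    params, indices = _canonicalise(alpha, b, idx.astype(np.int64))
    return params, indices, _max_residual_ppm(mz, params, indices)


def estimate_scan_ims(
    mz_values,
    seed_params: IMSParams | None = None,
    tolerance_ppm: float = 5.0,
    max_iter: int = 10,
) -> ScanEstimate:
    """Estimate the intrinsic mass spacing of one scan from its m/z vector.

    Successive differences of sqrt(m/z) are integer multiples of ``alpha`` on a
    lattice.  The smallest positive difference seeds ``alpha``; each difference
    is then rounded to its nearest multiple, provisional integer indices are
    accumulated, and (alpha, offset) refined by least squares of sqrt(m/z)
    against index until the index assignment is stable.  The result is
    canonicalised to gamma = 0 with |beta| <= alpha/2 so indices are absolute
    and comparable across scans.

    Parameters
    ----------
    mz_values : array-like
        Sorted, strictly increasing positive m/z values; at least 3 required
        (unless ``seed_params`` is given, in which case any number is placed
        directly on the seed lattice).
    seed_params : IMSParams, optional
        Warm start, e.g. the previous scan's estimate.
    tolerance_ppm : float
        Acceptance bound on the worst reconstruction residual.

    Raises
    ------
    UnderdeterminedError
        Fewer than 3 values and no seed.
    EstimationError
        No lattice found within ``tolerance_ppm``.
    """
    mz = np.asarray(mz_values, dtype=np.float64)
    if mz.ndim != 1:
        raise ValueError("mz_values must be one-dimensional")
    if np.any(mz <= 0):
        raise ValueError("m/z values must be positive")
    if np.any(np.diff(mz) <= 0):
        raise ValueError("m/z values must be sorted and distinct")

    r = np.sqrt(mz)

    if mz.size < 3:
        if seed_params is None:
            raise UnderdeterminedError(
                f"need at least 3 distinct m/z values to estimate IMS, got {mz.size}"
            )
        # under-determined: solve exactly on the seed's index assignment so the
        # stored lattice reproduces the observed values to rounding
        idx = round_half_away((r - seed_params.offset) / seed_params.alpha).astype(np.int64)
        if mz.size == 2 and idx[1] != idx[0]:
            alpha = float((r[1] - r[0]) / (idx[1] - idx[0]))
        else:
            alpha = seed_params.alpha
        b = float(r[0] - alpha * idx[0])
        params, indices = _canonicalise(alpha, b, idx)
        resid = _max_residual_ppm(mz, params, indices)
        if resid > tolerance_ppm:
            raise EstimationError(
                f"seeded lattice placement residual {resid:.3g} ppm exceeds "
                f"tolerance {tolerance_ppm} ppm",
                resid,
            )
        return ScanEstimate(params, indices, resid)

    if seed_params is not None:
        alpha = seed_params.alpha
        idx = round_half_away((r - seed_params.offset) / seed_params.alpha)
        params, indices, resid = _fit_lattice(mz, r, alpha, idx, max_iter)
    else:
        d = np.diff(r)
        # a spacing below this would need indices beyond unsigned 32-bit —
        # not a representable lattice, so the gcd must not shrink past it
        floor = float(r[-1]) / (2**32 - 1)
        # two seeding hypotheses that cannot be told apart a priori: the two
        # smallest differences may be one noisy multiple (seed at the
        # near-minimum cluster median, noise from its spread — the minimum of
        # many noisy unit-spacing differences is biased low and a stretched
        # candidate fits a false lattice) or two distinct exact multiples a few
        # percent apart (the cluster statistics are then meaningless; seed at
        # the minimum and assume rounding-level noise).  Solve under both and
        # keep whichever lattice reproduces the data better.
        d_min = float(d.min())
        candidates = []
        # hypothesis 1 — exact data: values sit on the lattice to float
        # rounding, so a nearest-integer Euclid fold recovers the spacing
        # directly; noise is rounding-level
        noise_exact = 1e-12 * d_min
        eps = 4.0 * float(np.spacing(r[-1]))
        alpha = _pairwise_gcd(d, eps=eps, noise=noise_exact, floor=floor)
        candidates.append((alpha, noise_exact))
        # hypothesis 2 — noisy data: the smallest differences are one noisy
        # multiple; seed the set-wide Euclid at the near-minimum cluster
        # median (the minimum of many noisy unit-spacing differences is
        # biased low and a stretched candidate fits a false lattice) with the
        # cluster spread as the noise scale.  With fewer than 3 members the
        # cluster statistics are meaningless — the smallest differences are
        # then distinct exact multiples and hypothesis 1 covers the scan.
        cluster = d[d <= 1.05 * d_min]
        if cluster.size >= 3:
            med = float(np.median(cluster))
            mad = 1.4826 * float(np.median(np.abs(cluster - med)))
            noise = max(mad, 1e-12 * med)
            candidates.append((_approx_gcd(d, med, noise, floor=floor), noise))
        best = None
        best_key = None
        for alpha, noise in candidates:
            if alpha <= floor:
                # fall back to the coarsest candidate so the residual reported
                # in the error below reflects the best representable lattice
                alpha = d_min
            alpha, _ = _refine_spacing(d, alpha, noise)
            k = np.maximum(round_half_away(d / alpha), 1.0)
            idx = np.concatenate([[0.0], np.cumsum(k)])
            fit = _fit_lattice(mz, r, alpha, idx, max_iter)
            # a finer spacing always lowers the raw residual (overfit), so a
            # candidate is preferred first for resolving its own quantisation
            # cell and meeting the tolerance, and only then for residual size
            cell = 1e6 * fit[0].alpha / float(r[-1])
            key = (not (fit[2] <= tolerance_ppm and fit[2] <= 0.5 * cell), fit[2])
            if best is None or key < best_key:
                best, best_key = fit, key
        params, indices, resid = best
    if resid > tolerance_ppm:
        raise EstimationError(
            f"no consistent lattice within {tolerance_ppm} ppm "
            f"(worst residual {resid:.3g} ppm)",
            resid,
        )
    # off-lattice data can always be overfitted by a fine enough spacing whose
    # quantisation cell swallows the scatter; a genuine lattice resolves its
    # points well inside its own cell (half-cell in m/z terms: alpha/sqrt(mz)),
    # while uniform scatter fills it, so half-cell residuals mean "no lattice"
    resolution_ppm = 1e6 * params.alpha / float(r[-1])
    if resid > 0.5 * resolution_ppm:
        raise EstimationError(
            f"residual {resid:.3g} ppm is not resolved by the fitted spacing "
            f"(cell {resolution_ppm:.3g} ppm): data are not on a lattice",
            resid,
        )
    return ScanEstimate(params, indices, resid)


def _max_residual_ppm(mz: np.ndarray, params: IMSParams, indices: np.ndarray) -> float:
    fit = np.square(params.alpha * (indices.astype(np.float64) + params.gamma) + params.beta)
    return float(np.max(np.abs(fit - mz) / mz) * 1e6)
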