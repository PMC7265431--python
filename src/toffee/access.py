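"""Random access into a window: spectra, extracted ion chromatograms, regions.

All three operations are pure views over the CSR arrays.  XIC band edges are
half-open ``[mz_low, mz_high)`` and are evaluated against each scan's own IMS
coefficients, so the integer bounds may legitimately differ from scan to scan;
a ``use_median_ims`` fast path evaluates the band once with the window-median
coefficients instead (approximate at the few-ppm level under drift).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .store import WindowMap, slice_scan

__all__ = ["Spectrum", "Chromatogram", "RegionRaster",
           "extract_spectrum", "extract_xic", "extract_region"]


@dataclass
class Spectrum:
    retention_time: float
    mz: np.ndarray
    intensity: np.ndarray


@dataclass
class Chromatogram:
    retention_time: np.ndarray
    intensity: np.ndarray


@dataclass
class RegionRaster:
    scan_range: tuple[int, int]  # half-open
    coord_range: tuple[int, int]  # half-open
    values: np.ndarray  # (scans, coords)


def extract_spectrum(window: WindowMap, scan_index: int) -> Spectrum:
    """The full spectrum of one scan, m/z reconstructed per-scan."""
    h = window.header
    if not 0 <= scan_index < window.n_scans:
        raise IndexError(f"scan {scan_index} out of range [0, {window.n_scans})")
    coords, inten = slice_scan(window.csr, scan_index)
    alpha = h.alphaPerScan[scan_index]
    beta = h.betaPerScan[scan_index]
    mz = np.square(alpha * (coords.astype(np.float64) + h.gamma) + beta)
    rt = h.firstScanRetentionTimeOffset + scan_index * h.scanCycleTime
    return Spectrum(retention_time=rt, mz=mz, intensity=inten.copy())


def _band_to_coords(mz_low, mz_high, alpha, beta, gamma):
    """Smallest half-open coordinate interval whose reconstructed m/z covers
    [mz_low, mz_high): include i iff mz_low <= mz(i) < mz_high."""
    lo = math.ceil((math.sqrt(mz_low) - beta) / alpha - gamma)
    hi = math.ceil((math.sqrt(mz_high) - beta) / alpha - gamma)
    return lo, hi


def extract_xic(
    window: WindowMap,
    mz_low: float,
    mz_high: float,
    scan_range: tuple[int, int] | None = None,
    use_median_ims: bool = False,
) -> Chromatogram:
    """Band-summed intensity per scan over ``[mz_low, mz_high)``."""
    if not mz_low < mz_high:
        raise ValueError(f"inverted m/z band [{mz_low}, {mz_high})")
    if mz_low <= 0:
        raise ValueError("mz_low must be positive")
    h = window.header
    s0, s1 = scan_range if scan_range is not None else (0, window.n_scans)
    if not (0 <= s0 <= s1 <= window.n_scans):
        raise IndexError(f"scan range [{s0}, {s1}) out of bounds")
    n = s1 - s0
    out = np.zeros(n, dtype=np.int64)
    if use_median_ims:
        lo_m, hi_m = _band_to_coords(mz_low, mz_high, h.medianAlpha, h.medianBeta, h.gamma)
    for k, si in enumerate(range(s0, s1)):
        coords, inten = slice_scan(window.csr, si)
        if use_median_ims:
            lo, hi = lo_m, hi_m
        else:
            lo, hi = _band_to_coords(
                mz_low, mz_high, h.alphaPerScan[si], h.betaPerScan[si], h.gamma
            )
        a = np.searchsorted(coords, lo, side="left")
        b = np.searchsorted(coords, hi, side="left")
        out[k] = int(inten[a:b].astype(np.int64).sum())
    rts = h.firstScanRetentionTimeOffset + np.arange(s0, s1) * h.scanCycleTime
    return Chromatogram(retention_time=rts, intensity=out)


def extract_region(
    window: WindowMap,
    scan_range: tuple[int, int],
    coord_range: tuple[int, int],
) -> RegionRaster:
    """Dense (scans x coords) raster of the stored intensities in a box."""
    s0, s1 = scan_range
    c0, c1 = coord_range
    if not (0 <= s0 < s1 <= window.n_scans):
        raise IndexError(f"scan range [{s0}, {s1}) out of bounds")
    if not (0 <= c0 < c1):
        raise IndexError(f"coordinate range [{c0}, {c1}) invalid")
    values = np.zeros((s1 - s0, c1 - c0), dtype=np.int64)
    for k, si in enumerate(range(s0, s1)):
        coords, inten = slice_scan(window.csr, si)
        a = np.searchsorted(coords, c0, side="left")
        b = np.searchsorted(coords, c1, side="left")
        values[k, coords[a:b].astype(np.int64) - c0] = inten[a:b]
    return RegionRaster(scan_range=(s0, s1), coord_range=(c0, c1), values=values)
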