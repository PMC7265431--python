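"""Peptide-centric 2D rasters for vision models.

A peptide is rendered as a stack of horizontal slices — one for the precursor
(MS1) and one per fragment (MS2) — each with three channels holding the
mono-isotope and the +1 and +2 isotope traces (offset by the 13C-12C mass
difference divided by charge).  The numeric rasters stay exact integer counts;
log-scaled 8-bit PNG export is a separate utility for qualitative inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .access import extract_region
from .ims import round_half_away
from .queries import PeptideQuery
from .store import RunModel, WindowMap

__all__ = [
    "CARBON_ISOTOPE_DELTA",
    "PeptideImage",
    "isotope_offsets",
    "render_peptide_image",
    "save_image_png",
]

# 13C - 12C mass difference, Da (CODATA atomic masses)
CARBON_ISOTOPE_DELTA = 1.0033548378


def isotope_offsets(mz: float, charge: int, k: int) -> float:
    """m/z of the k-th isotope peak of an ion at ``mz`` with ``charge``."""
    if charge < 1:
        raise ValueError("charge must be a positive integer")
    return mz + k * CARBON_ISOTOPE_DELTA / charge


@dataclass
class PeptideImage:
    """Stack of (3, n_scans, n_coords) channel rasters sharing one RT axis."""

    slices: list[np.ndarray]  # slice 0: precursor; 1..n: fragments
    rt_axis: np.ndarray
    coord_axes: list[list[tuple[int, int]]]  # per slice, per channel (start, stop)

    @property
    def n_slices(self) -> int:
        return len(self.slices)


def _center_coord(window: WindowMap, mz: float) -> int:
    h = window.header
    return int(round_half_away((np.sqrt(mz) - h.medianBeta) / h.medianAlpha - h.gamma))


def _scan_range(window: WindowMap, rt_window) -> tuple[int, int]:
    if rt_window is None:
        return 0, window.n_scans
    h = window.header
    lo, hi = rt_window
    s0 = int(np.ceil((lo - h.firstScanRetentionTimeOffset) / h.scanCycleTime))
    s1 = int(np.floor((hi - h.firstScanRetentionTimeOffset) / h.scanCycleTime)) + 1
    return max(s0, 0), min(s1, window.n_scans)


def _render_slice(window, center_mz, charge, scan_range, half_width):
    channels = []
    axes = []
    for k in range(3):
        c = _center_coord(window, isotope_offsets(center_mz, charge, k))
        c0 = max(c - half_width, 0)
        c1 = c + half_width + 1
        reg = extract_region(window, scan_range, (c0, c1))
        channels.append(reg.values)
        axes.append((c0, c1))
    return np.stack(channels), axes


def render_peptide_image(
    run: RunModel,
    query: PeptideQuery,
    rt_window: tuple[float, float] | None = None,
    coord_half_width: int = 10,
    fragment_charge: int = 1,
) -> PeptideImage:
    """Render the precursor and fragment isotope rasters of one peptide.

    ``rt_window=None`` keeps the full retention-time range.  Channel ``k`` of
    each slice is the dense region around the k-th isotope of that ion;
    fragment isotope offsets use ``fragment_charge`` (default 1).
    """
    ms2 = run.ms2_window_for(query.precursor_mz)
    ms1 = run.ms1
    s_ms1 = _scan_range(ms1, rt_window)
    s_ms2 = _scan_range(ms2, rt_window)
    n = min(s_ms1[1] - s_ms1[0], s_ms2[1] - s_ms2[0])
    if n <= 0:
        raise ValueError("retention-time window contains no scans")
    s_ms1 = (s_ms1[0], s_ms1[0] + n)
    s_ms2 = (s_ms2[0], s_ms2[0] + n)

    slices = []
    coord_axes = []
    chans, axes = _render_slice(ms1, query.precursor_mz, query.charge, s_ms1,
                                coord_half_width)
    slices.append(chans)
    coord_axes.append(axes)
    for fmz in query.fragment_mzs:
        chans, axes = _render_slice(ms2, fmz, fragment_charge, s_ms2, coord_half_width)
        slices.append(chans)
        coord_axes.append(axes)
    rts = (
        ms1.header.firstScanRetentionTimeOffset
        + np.arange(s_ms1[0], s_ms1[1]) * ms1.header.scanCycleTime
    )
    return PeptideImage(slices=slices, rt_axis=rts, coord_axes=coord_axes)


def save_image_png(image: PeptideImage, path, gap: int = 2) -> None:
    """Export the stacked slices as one log-scaled 8-bit RGB PNG."""
    from PIL import Image

    stacked = []
    width = max(s.shape[2] for s in image.slices)
    for s in image.slices:
        pad = width - s.shape[2]
        arr = np.pad(s, ((0, 0), (0, 0), (0, pad)))
        stacked.append(arr)
        stacked.append(np.zeros((3, gap, width), dtype=arr.dtype))
    full = np.concatenate(stacked[:-1], axis=1).astype(np.float64)
    full = np.log1p(full)
    peak = full.max()
    if peak > 0:
        full = full / peak * 255.0
    rgb = np.moveaxis(full, 0, -1).astype(np.uint8)
    Image.fromarray(rgb, mode="RGB").save(str(path))
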