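"""In-silico dilution series: move real peptide signal between runs.

Because every sample is an integer triplet on a Cartesian grid, the signal of
a chosen peptide can be cut out of a *foreground* run, scaled by a theoretical
dilution factor, and added to a *background* run at a known retention time.
The result is raw data of realistic complexity with exact ground truth, the
controlled input that peak-picking and scoring algorithms can be tested
against.  Foreground triplets are carried as m/z values (not raw coordinates)
so they can be re-gridded onto any background file's own per-scan lattice.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .access import extract_xic
from .ims import IMSParams, round_half_away
from .queries import PeptideQuery
from .store import RunModel, WindowMap, build_csr, slice_scan

__all__ = [
    "ForegroundTriplet",
    "ForegroundRegion",
    "GroundTruthEntry",
    "ConfusionCounts",
    "extract_foreground",
    "inject",
    "label_detections",
]


@dataclass
class ForegroundTriplet:
    scan_offset: int  # scans relative to the apex scan
    mz: float
    intensity: int
    is_ms1: bool
    fragment_index: int  # -1 for MS1


@dataclass
class ForegroundRegion:
    """A peptide's signal cut out of a foreground run, apex-relative."""

    query: PeptideQuery
    apex_rt: float
    triplets: list[ForegroundTriplet] = field(default_factory=list)

    def total_intensity(self) -> int:
        return sum(t.intensity for t in self.triplets)


@dataclass
class GroundTruthEntry:
    peptide: PeptideQuery
    injected_rt: float
    dilution_factor: float

    def __post_init__(self):
        if self.dilution_factor < 0:
            raise ValueError("dilution_factor must be non-negative")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int


def _scan_window_bounds(window: WindowMap, rt: float, half_width: float):
    h = window.header
    lo = int(np.ceil((rt - half_width - h.firstScanRetentionTimeOffset) / h.scanCycleTime))
    hi = int(np.floor((rt + half_width - h.firstScanRetentionTimeOffset) / h.scanCycleTime))
    return max(lo, 0), min(hi, window.n_scans - 1)


def _collect(window: WindowMap, mz_band, scan_lo, scan_hi, apex_scan,
             is_ms1, frag_idx, out):
    h = window.header
    lo_mz, hi_mz = mz_band
    for si in range(scan_lo, scan_hi + 1):
        coords, inten = slice_scan(window.csr, si)
        if coords.size == 0:
            continue
        alpha, beta = h.alphaPerScan[si], h.betaPerScan[si]
        mz = np.square(alpha * (coords.astype(np.float64) + h.gamma) + beta)
        sel = (mz >= lo_mz) & (mz < hi_mz)
        for mzv, v in zip(mz[sel], inten[sel]):
            out.append(
                ForegroundTriplet(
                    scan_offset=si - apex_scan,
                    mz=float(mzv),
                    intensity=int(v),
                    is_ms1=is_ms1,
                    fragment_index=frag_idx,
                )
            )


def extract_foreground(run: RunModel, query: PeptideQuery) -> ForegroundRegion:
    """Cut the query's MS1 and fragment signal out of ``run``, apex-centred.

    The apex is the scan maximising the summed fragment XIC inside the
    query's retention-time box; triplets within ``rt_half_width`` of the apex
    and within the ppm band of each target m/z are collected.
    """
    ms2 = run.ms2_window_for(query.precursor_mz)
    ms1 = run.ms1

    s_lo, s_hi = _scan_window_bounds(ms2, query.expected_rt, query.rt_half_width)
    if s_lo > s_hi:
        raise ValueError("query retention-time box lies outside the run")
    summed = np.zeros(s_hi - s_lo + 1, dtype=np.int64)
    for fmz in query.fragment_mzs:
        xic = extract_xic(ms2, *query.mz_band(fmz), scan_range=(s_lo, s_hi + 1))
        summed += xic.intensity
    apex_scan = s_lo + int(np.argmax(summed))
    apex_rt = float(
        ms2.header.firstScanRetentionTimeOffset + apex_scan * ms2.header.scanCycleTime
    )

    region = ForegroundRegion(query=query, apex_rt=apex_rt)
    a_lo, a_hi = _scan_window_bounds(ms2, apex_rt, query.rt_half_width)
    for j, fmz in enumerate(query.fragment_mzs):
        _collect(ms2, query.mz_band(fmz), a_lo, a_hi, apex_scan, False, j, region.triplets)
    m_lo, m_hi = _scan_window_bounds(ms1, apex_rt, query.rt_half_width)
    apex_ms1 = int(
        round_half_away(
            (apex_rt - ms1.header.firstScanRetentionTimeOffset) / ms1.header.scanCycleTime
        )
    )
    _collect(ms1, query.mz_band(query.precursor_mz), m_lo, m_hi, apex_ms1, True, -1,
             region.triplets)
    if not region.triplets:
        warnings.warn(
            f"empty foreground region for peptide {query.identifier}", stacklevel=2
        )
    return region


def inject(
    background: RunModel,
    region: ForegroundRegion,
    dilution_factor: float,
    target_rt: float,
) -> RunModel:
    """Add the scaled foreground signal to a copy of ``background`` at ``target_rt``.

    Intensities are scaled and rounded half-away-from-zero (entries rounding to
    zero are dropped, emulating the instrument's lower limit of detection);
    each triplet's m/z is re-indexed with the receiving scan's own IMS
    coefficients and placed at the nearest background scan to
    ``target_rt + scan_offset * cycle_time``.  Collisions sum; untouched cells
    are bit-identical to the background.
    """
    if dilution_factor < 0:
        raise ValueError("dilution_factor must be non-negative")
    out = copy.deepcopy(background)
    if dilution_factor == 0 or not region.triplets:
        return out

    ms2 = out.ms2_window_for(region.query.precursor_mz)
    targets = {True: out.ms1, False: ms2}
    new_triplets: dict[str, list] = {}
    for trip in region.triplets:
        w = targets[trip.is_ms1]
        h = w.header
        v = int(round_half_away(dilution_factor * trip.intensity))
        if v == 0:
            continue
        si = int(
            round_half_away(
                (target_rt + trip.scan_offset * h.scanCycleTime
                 - h.firstScanRetentionTimeOffset) / h.scanCycleTime
            )
        )
        si = min(max(si, 0), w.n_scans - 1)  # nearest scan, clamped at run edges
        alpha, beta = h.alphaPerScan[si], h.betaPerScan[si]
        coord = int(round_half_away((np.sqrt(trip.mz) - beta) / alpha - h.gamma))
        new_triplets.setdefault(w.name, []).append((si, coord, v))

    for name, extra in new_triplets.items():
        w = out.window(name)
        old = _csr_to_triplets(w)
        w.csr = build_csr(old + extra, n_scans=w.n_scans)
    return out


def _csr_to_triplets(w: WindowMap) -> list[tuple[int, int, int]]:
    out = []
    for si in range(w.n_scans):
        coords, inten = slice_scan(w.csr, si)
        out.extend((si, int(c), int(v)) for c, v in zip(coords, inten))
    return out


def label_detections(
    detections: list[tuple[str, float]],
    truth: list[GroundTruthEntry],
    rt_threshold: float = 10.0,
) -> ConfusionCounts:
    """Confusion counts of detections against constructed ground truth.

    A detection within ``rt_threshold`` seconds of its peptide's injected
    retention time is a true positive (duplicates per peptide resolved by
    nearest retention time: one TP per truth entry); every other detection is
    a false positive; truth entries with no matching detection are false
    negatives.
    """
    by_id: dict[str, list[int]] = {}
    for k, (pid, _) in enumerate(detections):
        by_id.setdefault(pid, []).append(k)
    known = {t.peptide.identifier for t in truth}
    for pid in by_id:
        if pid not in known:
            raise ValueError(f"detection for unknown peptide id {pid!r}")

    assigned = set()
    tp = fn = 0
    for t in truth:
        cands = [
            k
            for k in by_id.get(t.peptide.identifier, [])
            if k not in assigned and abs(detections[k][1] - t.injected_rt) <= rt_threshold
        ]
        if cands:
            best = min(cands, key=lambda k: abs(detections[k][1] - t.injected_rt))
            assigned.add(best)
            tp += 1
        else:
            fn += 1
    fp = len(detections) - tp
    return ConfusionCounts(tp=tp, fp=fp, fn=fn)


def ground_truth_table(entries: list[GroundTruthEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [e.peptide.identifier for e in entries],
            "injected_rt": [e.injected_rt for e in entries],
            "dilution_factor": [e.dilution_factor for e in entries],
        }
    )
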