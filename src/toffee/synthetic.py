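"""Deterministic synthetic DIA runs with exact ground truth.

Every generated sample lies exactly on its scan's integer lattice, with a
slow, bounded fractional drift of the per-scan coefficients emulating the
instrument's in-line calibration.  Peptides are placed as separable peaks —
Gaussian in log-retention-time, Gaussian in m/z index space — with a three
peak isotope envelope for the precursor and each fragment; background noise is
drawn at uniform lattice positions with exponentially distributed counts (a
pragmatic, explicitly non-physical stand-in for chemical noise).

The generator is the fixture for every cross-module oracle in the test suite:
it reports each peptide's true parameters and the exact total counts injected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .ims import IMSParams, round_half_away
from .queries import PeptideQuery
from .requant import FragmentRaster, PeakModelParams, eval_model
from .store import RunModel, WindowHeader, WindowMap, build_csr

__all__ = [
    "SyntheticPeptide",
    "SyntheticSpec",
    "GroundTruth",
    "default_spec",
    "generate_run",
    "generate_peak_raster",
    "spec_from_dict",
    "spec_to_dict",
]


@dataclass
class SyntheticPeptide:
    """One planted peptide: query plus true peak-shape parameters."""

    query: PeptideQuery
    apex_intensity: float = 500.0
    sigma_t: float = 0.02  # log-RT spread; ~2% of t0 as peak half-width scale
    sigma_m: float = 2.0  # index-space spread
    envelope: tuple = (1.0, 0.5, 0.2)  # isotope peak ratios
    fragment_rel: tuple | None = None  # per-fragment relative intensity

    def fragment_relatives(self) -> np.ndarray:
        if self.fragment_rel is not None:
            return np.asarray(self.fragment_rel, dtype=np.float64)
        n = len(self.query.fragment_mzs)
        return np.linspace(1.0, 0.4, n)


@dataclass
class SyntheticSpec:
    """Conditions of one synthetic acquisition."""

    seed: int = 0
    n_cycles: int = 60
    cycle_time: float = 3.0  # s, typical SWATH cycle
    rt_start: float = 10.0  # s, first MS1 scan
    ms2_windows: tuple = ((400.0, 500.0), (500.0, 600.0), (600.0, 700.0))
    alpha: float = 7.5e-5  # sqrt(Da) per index step: ~6.7 ppm at m/z 500, TOF-like
    beta: float = 0.0
    drift: float = 1e-6  # fractional per-scan bound on alpha/beta drift
    peptides: list[SyntheticPeptide] = field(default_factory=list)
    noise_rate: float = 50.0  # expected background samples per scan per window
    noise_mean_intensity: float = 4.0
    ms1_mz_range: tuple = (380.0, 720.0)
    ms2_mz_range: tuple = (100.0, 1000.0)

    def __post_init__(self):
        wins = list(self.ms2_windows)
        for (l0, u0), (l1, u1) in zip(wins, wins[1:]):
            if not (l0 < u0 <= l1 < u1):
                raise ValueError("ms2_windows must be ordered and non-overlapping")
        if self.drift < 0:
            raise ValueError("drift must be non-negative")
        for p in self.peptides:
            lo = self.ms2_windows[0][0]
            hi = self.ms2_windows[-1][1]
            if not (lo <= p.query.precursor_mz < hi):
                raise ValueError(
                    f"peptide {p.query.identifier}: precursor m/z "
                    f"{p.query.precursor_mz} outside all MS2 windows"
                )


@dataclass
class GroundTruth:
    peptides: pd.DataFrame  # one row per peptide: true params + exact totals
    noise_total: int
    total: int


def default_spec(seed: int = 0, n_cycles: int = 60, n_peptides: int = 4,
                 drift: float = 1e-6, noise_rate: float = 50.0) -> SyntheticSpec:
    """A realistic small acquisition: 3 windows, a handful of peptides."""
    rng = np.random.default_rng(seed)
    spec = SyntheticSpec(seed=seed, n_cycles=n_cycles, drift=drift,
                         noise_rate=noise_rate)
    t_span = spec.rt_start + spec.cycle_time * n_cycles
    for k in range(n_peptides):
        prec = float(rng.uniform(410, 690))
        frags = np.sort(rng.uniform(200, 950, size=4))
        rt = float(rng.uniform(0.25, 0.75) * t_span)
        q = PeptideQuery(
            identifier=f"PEP{k:03d}",
            precursor_mz=prec,
            charge=2,
            fragment_mzs=frags,
            expected_rt=rt,
        )
        spec.peptides.append(
            SyntheticPeptide(
                query=q,
                apex_intensity=float(rng.uniform(300, 1500)),
                sigma_t=float(rng.uniform(0.015, 0.03)),
                sigma_m=float(rng.uniform(1.5, 3.0)),
            )
        )
    return spec


def _drift_series(rng, n, bound):
    """Smooth low-frequency fractional drift in [-bound, bound]."""
    if bound == 0 or n == 1:
        return np.zeros(n)
    s = np.arange(n) / max(n - 1, 1)
    ph = rng.uniform(0, 2 * np.pi, size=2)
    raw = 0.7 * np.sin(2 * np.pi * 1.0 * s + ph[0]) + 0.3 * np.sin(
        2 * np.pi * 2.3 * s + ph[1]
    )
    return bound * raw


def _peak_triplets(spec, pept, center_mzs, amplitudes, t0, rts):
    """Integerised separable peak: returns [(scan, coord, count), ...] and total."""
    trips = []
    tfac = np.exp(-((np.log(rts) - np.log(t0)) ** 2) / (2.0 * pept.sigma_t**2))
    half = int(np.ceil(4.0 * pept.sigma_m))
    for mz, amp in zip(center_mzs, amplitudes):
        c0 = int(round_half_away((np.sqrt(mz) - spec.beta) / spec.alpha))
        coords = np.arange(c0 - half, c0 + half + 1)
        mfac = np.exp(-((coords - c0) ** 2) / (2.0 * pept.sigma_m**2))
        grid = round_half_away(amp * np.outer(tfac, mfac))
        sc, cc = np.nonzero(grid > 0)
        for s, c in zip(sc, cc):
            trips.append((int(s), int(coords[c]), int(grid[s, c])))
    return trips


def generate_run(spec: SyntheticSpec) -> tuple[RunModel, GroundTruth]:
    """Generate a grid-consistent run and its exact ground truth.

    Deterministic given ``spec.seed``; every sample lies on its scan's
    lattice by construction (samples are stored as integer coordinates and
    m/z is only ever reconstructed through the transfer function).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cycles
    n_windows = 1 + len(spec.ms2_windows)
    sub_dt = spec.cycle_time / n_windows

    # window definitions: (name, lower, center, upper, rt offset, mz span)
    defs = [("ms1", -1.0, -1.0, -1.0, spec.rt_start, spec.ms1_mz_range)]
    for k, (lo, hi) in enumerate(spec.ms2_windows):
        defs.append(
            (f"ms2-{k + 1:03d}", lo, 0.5 * (lo + hi), hi,
             spec.rt_start + (k + 1) * sub_dt, spec.ms2_mz_range)
        )

    # per-window per-scan IMS with smooth drift, canonical (gamma=0, |beta|<alpha/2)
    ims = {}
    for name, *_ in defs:
        alphas = spec.alpha * (1.0 + _drift_series(rng, n, spec.drift))
        betas = spec.beta + spec.alpha * _drift_series(rng, n, spec.drift)
        ims[name] = (alphas, betas)

    window_triplets = {name: [] for name, *_ in defs}
    rows = []
    from .imaging import isotope_offsets

    for pept in spec.peptides:
        q = pept.query
        t0 = q.expected_rt
        ms2_name = None
        for name, lo, _c, hi, _rt, _span in defs[1:]:
            if lo <= q.precursor_mz < hi:
                ms2_name = name
                break
        assert ms2_name is not None  # guaranteed by SyntheticSpec validation
        contributions = 0
        # precursor isotopes into ms1
        rts_ms1 = defs[0][4] + np.arange(n) * spec.cycle_time
        centers = [isotope_offsets(q.precursor_mz, q.charge, k) for k in range(3)]
        amps = [pept.apex_intensity * e for e in pept.envelope]
        trips = _peak_triplets(spec, pept, centers, amps, t0, rts_ms1)
        window_triplets["ms1"].extend(trips)
        contributions += sum(t[2] for t in trips)
        # fragment isotopes into the matching ms2 window
        rt_off = next(d[4] for d in defs if d[0] == ms2_name)
        rts_ms2 = rt_off + np.arange(n) * spec.cycle_time
        for fmz, rel in zip(q.fragment_mzs, pept.fragment_relatives()):
            centers = [isotope_offsets(float(fmz), 1, k) for k in range(3)]
            amps = [pept.apex_intensity * rel * e for e in pept.envelope]
            trips = _peak_triplets(spec, pept, centers, amps, t0, rts_ms2)
            window_triplets[ms2_name].extend(trips)
            contributions += sum(t[2] for t in trips)
        rows.append(
            {
                "id": q.identifier,
                "precursor_mz": q.precursor_mz,
                "charge": q.charge,
                "ms2_window": ms2_name,
                "t0": t0,
                "sigma_t": pept.sigma_t,
                "sigma_m": pept.sigma_m,
                "apex_intensity": pept.apex_intensity,
                "total_intensity": contributions,
            }
        )

    # background noise: uniform lattice positions, exponential counts
    noise_total = 0
    for name, _lo, _c, _hi, _rt, span in defs:
        if spec.noise_rate <= 0:
            continue
        c_lo = int(round_half_away((np.sqrt(span[0]) - spec.beta) / spec.alpha))
        c_hi = int(round_half_away((np.sqrt(span[1]) - spec.beta) / spec.alpha))
        for s in range(n):
            k = rng.poisson(spec.noise_rate)
            if k == 0:
                continue
            coords = rng.integers(c_lo, c_hi, size=k)
            counts = 1 + np.floor(rng.exponential(spec.noise_mean_intensity, size=k)).astype(int)
            window_triplets[name].extend(
                (s, int(c), int(v)) for c, v in zip(coords, counts)
            )
            noise_total += int(counts.sum())

    windows = []
    for name, lo, center, hi, rt_off, _span in defs:
        alphas, betas = ims[name]
        header = WindowHeader(
            name=name,
            precursorLower=lo,
            precursorCenter=center,
            precursorUpper=hi,
            firstScanRetentionTimeOffset=rt_off,
            scanCycleTime=spec.cycle_time,
            medianAlpha=float(np.median(alphas)),
            medianBeta=float(np.median(betas)),
            gamma=0,
            alphaPerScan=alphas,
            betaPerScan=betas,
        )
        windows.append(
            WindowMap(header=header, csr=build_csr(window_triplets[name], n_scans=n))
        )
    from .mzml import _build_metadata_xml

    run = RunModel(windows=windows, metadataXML=_build_metadata_xml(windows))
    run.validate()
    truth = GroundTruth(
        peptides=pd.DataFrame(rows),
        noise_total=noise_total,
        total=run.total_intensity(),
    )
    return run, truth


def generate_peak_raster(
    params: PeakModelParams,
    t: np.ndarray,
    m: np.ndarray,
    noise_sigma: float = 0.0,
    seed: int = 0,
    is_ms1=None,
) -> FragmentRaster:
    """Model raster plus seeded Gaussian noise, zero-truncated."""
    J = params.n_fragments
    if is_ms1 is None:
        is_ms1 = np.zeros(J, dtype=bool)
    is_ms1 = np.atleast_1d(np.asarray(is_ms1, dtype=bool))
    rng = np.random.default_rng(seed)
    stack = np.stack(
        [eval_model(params, t, m, j, is_ms1=bool(is_ms1[j])) for j in range(J)]
    )
    if noise_sigma > 0:
        stack = stack + rng.normal(0.0, noise_sigma, size=stack.shape)
    stack = np.clip(stack, 0.0, None)
    return FragmentRaster(t=np.asarray(t, float), m=np.asarray(m, float),
                         I=stack, is_ms1=is_ms1)


# --- YAML-friendly (de)serialisation used by the fixture CLI -----------------


def spec_to_dict(spec: SyntheticSpec) -> dict:
    d = asdict(spec)
    d["ms2_windows"] = [list(w) for w in spec.ms2_windows]
    d["peptides"] = []
    for p in spec.peptides:
        q = p.query
        d["peptides"].append(
            {
                "id": q.identifier,
                "precursor_mz": q.precursor_mz,
                "charge": q.charge,
                "fragment_mzs": [float(x) for x in q.fragment_mzs],
                "expected_rt": q.expected_rt,
                "rt_half_width": q.rt_half_width,
                "mz_half_width_ppm": q.mz_half_width_ppm,
                "apex_intensity": p.apex_intensity,
                "sigma_t": p.sigma_t,
                "sigma_m": p.sigma_m,
                "envelope": list(p.envelope),
                "fragment_rel": list(p.fragment_rel) if p.fragment_rel else None,
            }
        )
    return d


def spec_from_dict(d: dict) -> SyntheticSpec:
    d = dict(d)
    peps = []
    for p in d.pop("peptides", []):
        p = dict(p)
        q = PeptideQuery(
            identifier=str(p.pop("id")),
            precursor_mz=float(p.pop("precursor_mz")),
            charge=int(p.pop("charge")),
            fragment_mzs=np.asarray(p.pop("fragment_mzs"), dtype=float),
            expected_rt=float(p.pop("expected_rt")),
            rt_half_width=float(p.pop("rt_half_width", 30.0)),
            mz_half_width_ppm=float(p.pop("mz_half_width_ppm", 50.0)),
        )
        frag_rel = p.pop("fragment_rel", None)
        peps.append(
            SyntheticPeptide(
                query=q,
                apex_intensity=float(p.pop("apex_intensity", 500.0)),
                sigma_t=float(p.pop("sigma_t", 0.02)),
                sigma_m=float(p.pop("sigma_m", 2.0)),
                envelope=tuple(p.pop("envelope", (1.0, 0.5, 0.2))),
                fragment_rel=tuple(frag_rel) if frag_rel else None,
            )
        )
    d["ms2_windows"] = tuple(tuple(w) for w in d.get("ms2_windows",
                                                     SyntheticSpec.ms2_windows))
    for key in ("ms1_mz_range", "ms2_mz_range"):
        if key in d:
            d[key] = tuple(d[key])
    return SyntheticSpec(peptides=peps, **d)
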