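"""Sparse per-window storage and its HDF5 persistence.

One acquisition run is a collection of isolation windows (one MS1 plus the
cyclic MS2 windows).  Each window holds its scans as a compressed-sparse-row
matrix: rows are scans, columns are integer m/z indices, values are integer
ion counts.  The row pointer (``retentionTimeIdx``) stores, per scan, the
exclusive end offset into the coordinate/intensity vectors — the file keeps no
leading zero entry.

On disk every window is one HDF5 group.  Attribute and dataset names, and the
unsigned 32-bit dtypes of the three CSR vectors, are part of the format and
are validated on read.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import scipy.sparse

from ._errors import CorruptFileError, FormatVersionError, StorageOverflowError

__all__ = [
    "CSRMap",
    "WindowHeader",
    "WindowMap",
    "RunModel",
    "build_csr",
    "slice_scan",
    "write_toffee",
    "read_toffee",
    "format_manifest",
    "LIBRARY_VERSION",
    "FORMAT_MAJOR",
    "FORMAT_MINOR",
]

LIBRARY_VERSION = "toffee-py 0.1.0"
FORMAT_MAJOR = 1
FORMAT_MINOR = 0


def format_manifest() -> dict:
    """The checked-in on-disk layout contract: exact attribute/dataset names
    and dtypes every toffee file must carry."""
    import importlib.resources
    import json

    text = (
        importlib.resources.files("toffee")
        .joinpath("format_manifest.json")
        .read_text(encoding="utf-8")
    )
    return json.loads(text)

_U32_MAX = np.iinfo(np.uint32).max

_ROOT_ATTRS = (
    "CREATED_BY_LIBRARY_VERSION",
    "FILE_FORMAT_MAJOR_VERSION",
    "FILE_FORMAT_MINOR_VERSION",
    "IMSType",
    "metadataXML",
)
_WINDOW_ATTRS = (
    "IMSAlpha",
    "IMSBeta",
    "IMSGamma",
    "firstScanRetentionTimeOffset",
    "scanCycleTime",
    "precursorLower",
    "precursorCenter",
    "precursorUpper",
)
_WINDOW_DATASETS = (
    "IMSAlphaPerScan",
    "IMSBetaPerScan",
    "retentionTimeIdx",
    "imsCoord",
    "intensity",
)


@dataclass
class CSRMap:
    """CSR triplet store of one window: scans x integer m/z coordinates."""

    retentionTimeIdx: np.ndarray  # uint32, one exclusive-end offset per scan
    imsCoord: np.ndarray  # uint32
    intensity: np.ndarray  # uint32

    @property
    def n_scans(self) -> int:
        return len(self.retentionTimeIdx)

    def validate(self) -> None:
        rti, coord, inten = self.retentionTimeIdx, self.imsCoord, self.intensity
        if len(coord) != len(inten):
            raise CorruptFileError("imsCoord and intensity lengths differ")
        if len(rti) and rti[-1] != len(coord):
            raise CorruptFileError(
                "final retentionTimeIdx entry does not equal the number of samples"
            )
        if np.any(np.diff(rti.astype(np.int64)) < 0):
            raise CorruptFileError("retentionTimeIdx is not non-decreasing")
        if np.any(inten == 0):
            raise CorruptFileError("zero-intensity samples are not stored")
        start = 0
        for end in rti:
            seg = coord[start:end].astype(np.int64)
            if np.any(np.diff(seg) <= 0):
                raise CorruptFileError("imsCoord not strictly increasing within a scan")
            start = end

    def total_intensity(self) -> int:
        return int(self.intensity.astype(np.uint64).sum())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CSRMap)
            and np.array_equal(self.retentionTimeIdx, other.retentionTimeIdx)
            and np.array_equal(self.imsCoord, other.imsCoord)
            and np.array_equal(self.intensity, other.intensity)
        )


@dataclass
class WindowHeader:
    """Per-window metadata: precursor bounds, retention-time model, IMS arrays."""

    name: str  # "ms1" or "ms2-NNN"
    precursorLower: float
    precursorCenter: float
    precursorUpper: float
    firstScanRetentionTimeOffset: float
    scanCycleTime: float
    medianAlpha: float
    medianBeta: float
    gamma: int
    alphaPerScan: np.ndarray
    betaPerScan: np.ndarray

    @property
    def n_scans(self) -> int:
        return len(self.alphaPerScan)

    @property
    def is_ms1(self) -> bool:
        return self.name == "ms1"

    def scan_retention_times(self) -> np.ndarray:
        return (
            self.firstScanRetentionTimeOffset
            + np.arange(self.n_scans, dtype=np.float64) * self.scanCycleTime
        )

    def validate(self) -> None:
        if len(self.alphaPerScan) != len(self.betaPerScan):
            raise CorruptFileError("alphaPerScan and betaPerScan lengths differ")
        if not self.scanCycleTime > 0:
            raise CorruptFileError("scanCycleTime must be positive")
        if self.is_ms1:
            if not (
                self.precursorLower == -1
                and self.precursorCenter == -1
                and self.precursorUpper == -1
            ):
                raise CorruptFileError("MS1 precursor bounds must all be -1")
        else:
            if not (self.precursorLower < self.precursorCenter < self.precursorUpper):
                raise CorruptFileError(
                    f"window {self.name}: precursor bounds not ordered"
                )

    def equals(self, other: "WindowHeader", rtol: float = 0.0,
               scan_mask: np.ndarray | None = None) -> bool:
        scalars_self = (
            self.precursorLower,
            self.precursorCenter,
            self.precursorUpper,
            self.firstScanRetentionTimeOffset,
            self.scanCycleTime,
        )
        scalars_other = (
            other.precursorLower,
            other.precursorCenter,
            other.precursorUpper,
            other.firstScanRetentionTimeOffset,
            other.scanCycleTime,
        )
        if self.name != other.name or self.gamma != other.gamma:
            return False
        if rtol == 0.0:
            return (
                scalars_self == scalars_other
                and self.medianAlpha == other.medianAlpha
                and self.medianBeta == other.medianBeta
                and np.array_equal(self.alphaPerScan, other.alphaPerScan)
                and np.array_equal(self.betaPerScan, other.betaPerScan)
            )
        # beta may pass through zero and is only identified to ~1e-9 sqrt(Da)
        # (intercept lever arm), so it gets a fixed absolute tolerance
        beta_atol = 1e-9
        if not np.allclose(scalars_self, scalars_other, rtol=rtol, atol=0):
            return False
        # the IMS of a data-free scan is unidentifiable, so when a mask of
        # populated scans is supplied the coefficient comparison (including
        # the medians, re-derived on the mask) is restricted to it
        if scan_mask is None:
            scan_mask = np.ones(len(self.alphaPerScan), dtype=bool)
        if not scan_mask.any():
            return True
        a_s, a_o = self.alphaPerScan[scan_mask], other.alphaPerScan[scan_mask]
        b_s, b_o = self.betaPerScan[scan_mask], other.betaPerScan[scan_mask]
        if scan_mask.all():
            med_ok = np.isclose(
                self.medianAlpha, other.medianAlpha, rtol=rtol, atol=0
            ) and np.isclose(self.medianBeta, other.medianBeta, rtol=0, atol=beta_atol)
        else:
            med_ok = np.isclose(
                np.median(a_s), np.median(a_o), rtol=rtol, atol=0
            ) and np.isclose(np.median(b_s), np.median(b_o), rtol=0, atol=beta_atol)
        return bool(
            med_ok
            and np.allclose(a_s, a_o, rtol=rtol, atol=0)
            and np.allclose(b_s, b_o, rtol=0, atol=beta_atol)
        )


@dataclass
class WindowMap:
    """One isolation window: header plus CSR store."""

    header: WindowHeader
    csr: CSRMap

    @property
    def name(self) -> str:
        return self.header.name

    @property
    def n_scans(self) -> int:
        return self.header.n_scans

    def validate(self) -> None:
        self.header.validate()
        self.csr.validate()
        if self.csr.n_scans != self.header.n_scans:
            raise CorruptFileError(
                f"window {self.name}: CSR has {self.csr.n_scans} scans but header "
                f"declares {self.header.n_scans}"
            )


@dataclass
class RunModel:
    """In-memory image of one toffee file."""

    windows: list[WindowMap] = field(default_factory=list)
    createdByVersion: str = LIBRARY_VERSION
    formatMajor: int = FORMAT_MAJOR
    formatMinor: int = FORMAT_MINOR
    imsType: str = "TOF"
    metadataXML: str = ""

    def validate(self) -> None:
        names = [w.name for w in self.windows]
        if names.count("ms1") != 1:
            raise CorruptFileError("exactly one window must be named 'ms1'")
        ms2 = [n for n in names if n != "ms1"]
        expected = [f"ms2-{k:03d}" for k in range(1, len(ms2) + 1)]
        if sorted(ms2) != expected:
            raise CorruptFileError(
                f"MS2 windows must be named contiguously ms2-001..: got {sorted(ms2)}"
            )
        for w in self.windows:
            w.validate()

    def window(self, name: str) -> WindowMap:
        for w in self.windows:
            if w.name == name:
                return w
        raise KeyError(name)

    @property
    def ms1(self) -> WindowMap:
        return self.window("ms1")

    def ms2_windows(self) -> list[WindowMap]:
        return sorted(
            (w for w in self.windows if not w.header.is_ms1), key=lambda w: w.name
        )

    def ms2_window_for(self, precursor_mz: float) -> WindowMap:
        """The MS2 window whose isolation bounds contain ``precursor_mz``."""
        from ._errors import WindowResolutionError

        for w in self.ms2_windows():
            if w.header.precursorLower <= precursor_mz < w.header.precursorUpper:
                return w
        raise WindowResolutionError(
            f"precursor m/z {precursor_mz} falls in no MS2 isolation window"
        )

    def total_intensity(self) -> int:
        return sum(w.csr.total_intensity() for w in self.windows)

    def equals(self, other: "RunModel", rtol: float = 0.0) -> bool:
        """Field-by-field equality; ``rtol`` relaxes only the per-scan IMS floats."""
        if (
            self.formatMajor != other.formatMajor
            or self.formatMinor != other.formatMinor
            or self.imsType != other.imsType
            or len(self.windows) != len(other.windows)
        ):
            return False
        for a, b in zip(self.windows, other.windows):
            if a.csr != b.csr:
                return False
            mask = None
            if rtol > 0.0:
                rti = a.csr.retentionTimeIdx.astype(np.int64)
                mask = np.diff(np.concatenate([[0], rti])) > 0
            if not a.header.equals(b.header, rtol=rtol, scan_mask=mask):
                return False
        return True


def build_csr(triplets, n_scans: int) -> CSRMap:
    """Assemble (scan, coordinate, intensity) triplets into a CSR map.

    Duplicate (scan, coordinate) pairs are summed; zero intensities dropped;
    coordinates sorted within each scan.  Empty scans are permitted.
    """
    if n_scans < 0:
        raise ValueError("n_scans must be non-negative")
    trip = np.asarray(list(triplets) if not isinstance(triplets, np.ndarray) else triplets)
    if trip.size == 0:
        return CSRMap(
            retentionTimeIdx=np.zeros(n_scans, dtype=np.uint32),
            imsCoord=np.zeros(0, dtype=np.uint32),
            intensity=np.zeros(0, dtype=np.uint32),
        )
    trip = trip.reshape(-1, 3)
    scans = trip[:, 0].astype(np.int64)
    coords = trip[:, 1].astype(np.int64)
    inten = trip[:, 2].astype(np.int64)
    if np.any((scans < 0) | (scans >= n_scans)):
        raise ValueError("scan_index out of range")
    if np.any(coords < 0) or np.any(inten < 0):
        raise ValueError("coordinates and intensities must be non-negative")

    # scipy's COO->CSR sums duplicates and sorts columns within rows
    width = int(coords.max()) + 1 if coords.size else 1
    mat = scipy.sparse.coo_matrix(
        (inten.astype(np.int64), (scans, coords)), shape=(n_scans, width)
    ).tocsr()
    mat.sum_duplicates()
    mat.eliminate_zeros()
    mat.sort_indices()

    _check_u32(mat.indices, "imsCoord")
    _check_u32(mat.data, "intensity")
    return CSRMap(
        retentionTimeIdx=mat.indptr[1:].astype(np.uint32),
        imsCoord=mat.indices.astype(np.uint32),
        intensity=mat.data.astype(np.uint32),
    )


def slice_scan(csr: CSRMap, scan_index: int):
    """The (coordinates, intensities) of one scan, as views into the CSR arrays."""
    if not 0 <= scan_index < csr.n_scans:
        raise IndexError(f"scan {scan_index} out of range [0, {csr.n_scans})")
    start = int(csr.retentionTimeIdx[scan_index - 1]) if scan_index > 0 else 0
    end = int(csr.retentionTimeIdx[scan_index])
    return csr.imsCoord[start:end], csr.intensity[start:end]


def _check_u32(arr, what: str, window: str | None = None, scan=None) -> None:
    if arr.size and (int(arr.max()) > _U32_MAX or int(arr.min()) < 0):
        where = f" in window {window}" if window else ""
        where += f", scan {scan}" if scan is not None else ""
        raise StorageOverflowError(f"{what} exceeds unsigned 32-bit range{where}")


def write_toffee(run: RunModel, path, compression_level: int = 6) -> None:
    """Persist a run to HDF5 with the canonical group/attribute/dataset layout."""
    run.validate()
    with h5py.File(path, "w") as f:
        f.attrs["CREATED_BY_LIBRARY_VERSION"] = run.createdByVersion
        f.attrs["FILE_FORMAT_MAJOR_VERSION"] = np.int64(run.formatMajor)
        f.attrs["FILE_FORMAT_MINOR_VERSION"] = np.int64(run.formatMinor)
        f.attrs["IMSType"] = run.imsType
        f.attrs["metadataXML"] = run.metadataXML
        for w in run.windows:
            h = w.header
            for arr, what in ((w.csr.imsCoord, "imsCoord"), (w.csr.intensity, "intensity")):
                _check_u32(arr.astype(np.int64), what, window=w.name)
            g = f.create_group(w.name)
            g.attrs["IMSAlpha"] = float(h.medianAlpha)
            g.attrs["IMSBeta"] = float(h.medianBeta)
            g.attrs["IMSGamma"] = np.int64(h.gamma)
            g.attrs["firstScanRetentionTimeOffset"] = float(h.firstScanRetentionTimeOffset)
            g.attrs["scanCycleTime"] = float(h.scanCycleTime)
            g.attrs["precursorLower"] = float(h.precursorLower)
            g.attrs["precursorCenter"] = float(h.precursorCenter)
            g.attrs["precursorUpper"] = float(h.precursorUpper)
            opts = dict(compression="gzip", compression_opts=int(compression_level))
            g.create_dataset("IMSAlphaPerScan", data=h.alphaPerScan.astype(np.float64), **opts)
            g.create_dataset("IMSBetaPerScan", data=h.betaPerScan.astype(np.float64), **opts)
            g.create_dataset("retentionTimeIdx", data=w.csr.retentionTimeIdx.astype(np.uint32), **opts)
            g.create_dataset("imsCoord", data=w.csr.imsCoord.astype(np.uint32), **opts)
            g.create_dataset("intensity", data=w.csr.intensity.astype(np.uint32), **opts)


def read_toffee(path) -> RunModel:
    """Load and fully validate a run from HDF5.

    Raises
    ------
    FormatVersionError
        Unsupported major format version.
    CorruptFileError
        Any missing member or violated invariant, naming the failure.
    """
    with h5py.File(path, "r") as f:
        for a in _ROOT_ATTRS:
            if a not in f.attrs:
                raise CorruptFileError(f"missing root attribute {a!r}")
        major = int(f.attrs["FILE_FORMAT_MAJOR_VERSION"])
        if major != FORMAT_MAJOR:
            raise FormatVersionError(
                f"unsupported major format version {major} (supported: {FORMAT_MAJOR})"
            )
        names = sorted(f.keys())
        if "ms1" not in names:
            raise CorruptFileError("missing group 'ms1'")
        windows = []
        for name in ["ms1"] + [n for n in names if n != "ms1"]:
            g = f[name]
            for a in _WINDOW_ATTRS:
                if a not in g.attrs:
                    raise CorruptFileError(f"window {name}: missing attribute {a!r}")
            for d in _WINDOW_DATASETS:
                if d not in g:
                    raise CorruptFileError(f"window {name}: missing dataset {d!r}")
            header = WindowHeader(
                name=name,
                precursorLower=float(g.attrs["precursorLower"]),
                precursorCenter=float(g.attrs["precursorCenter"]),
                precursorUpper=float(g.attrs["precursorUpper"]),
                firstScanRetentionTimeOffset=float(g.attrs["firstScanRetentionTimeOffset"]),
                scanCycleTime=float(g.attrs["scanCycleTime"]),
                medianAlpha=float(g.attrs["IMSAlpha"]),
                medianBeta=float(g.attrs["IMSBeta"]),
                gamma=int(g.attrs["IMSGamma"]),
                alphaPerScan=g["IMSAlphaPerScan"][...].astype(np.float64),
                betaPerScan=g["IMSBetaPerScan"][...].astype(np.float64),
            )
            csr = CSRMap(
                retentionTimeIdx=g["retentionTimeIdx"][...],
                imsCoord=g["imsCoord"][...],
                intensity=g["intensity"][...],
            )
            for ds, arr in (("retentionTimeIdx", csr.retentionTimeIdx),
                            ("imsCoord", csr.imsCoord),
                            ("intensity", csr.intensity)):
                if arr.dtype != np.uint32:
                    raise CorruptFileError(
                        f"window {name}: dataset {ds} has dtype {arr.dtype}, expected uint32"
                    )
            windows.append(WindowMap(header=header, csr=csr))
        run = RunModel(
            windows=windows,
            createdByVersion=str(f.attrs["CREATED_BY_LIBRARY_VERSION"]),
            formatMajor=major,
            formatMinor=int(f.attrs["FILE_FORMAT_MINOR_VERSION"]),
            imsType=str(f.attrs["IMSType"]),
            metadataXML=str(f.attrs["metadataXML"]),
        )
    run.validate()
    return run
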