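"""Conversion between profile mzML spectra and the integer-grid run model.

``import_run`` estimates per-scan intrinsic mass spacing, places every sample
on its scan's integer lattice and builds one CSR window per isolation window.
``export_run`` inverts this: m/z is reconstructed from each scan's own
coefficients, retention times from the per-window linear model, intensities as
stored.  For grid-consistent profile input the round trip preserves every
non-zero sample (intensities exactly; m/z to double-precision rounding of the
fitted transfer function).

File-level I/O: reading goes through :mod:`pyteomics.mzml`; writing emits a
minimal profile mzML 1.1 document (zlib-compressed 64-bit binary arrays for
both axes, so integer counts survive exactly).
"""

from __future__ import annotations

import base64
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
from lxml import etree

from ._errors import LossyInputError, StructureError
from .ims import IMSParams, estimate_scan_ims, round_half_away
from .store import (
    CSRMap,
    RunModel,
    WindowHeader,
    WindowMap,
    build_csr,
    slice_scan,
)

__all__ = [
    "SpectrumRecord",
    "import_run",
    "export_run",
    "read_mzml",
    "write_mzml",
]


@dataclass
class SpectrumRecord:
    """One profile spectrum: the mzML-level abstraction exchanged with files."""

    ms_level: int
    retention_time: float  # seconds
    mz: np.ndarray
    intensity: np.ndarray
    precursor_lower: float | None = None
    precursor_center: float | None = None
    precursor_upper: float | None = None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz must be strictly increasing")


def _window_key(s: SpectrumRecord):
    return None if s.ms_level == 1 else (s.precursor_lower, s.precursor_upper)


def import_run(
    spectra,
    tolerance_ppm: float = 5.0,
    strict: bool = True,
) -> RunModel:
    """Build a :class:`RunModel` from acquisition-ordered profile spectra.

    Spectra are grouped into cycles (each MS1 scan opens a cycle followed by
    the same set of MS2 isolation windows).  Per scan, IMS coefficients are
    estimated with the previous scan of the same window as warm start; a scan
    whose m/z values cannot be placed on a lattice within ``tolerance_ppm``
    raises :class:`LossyInputError` (profile TOF data is grid-consistent;
    centroided input typically is not).

    With ``strict=False`` intensity integerisation deviations beyond 1e-6 are
    still warnings, but sub-tolerance lattice residuals never raise.
    """
    spectra = list(spectra)
    if not spectra:
        raise StructureError("no spectra")
    if spectra[0].ms_level != 1:
        raise StructureError("run must start with an MS1 spectrum")

    # --- group into cycles and check the window structure is consistent
    cycles: list[list[SpectrumRecord]] = []
    for s in spectra:
        if s.ms_level == 1:
            cycles.append([s])
        else:
            if not cycles:
                raise StructureError("MS2 spectrum before any MS1 spectrum")
            cycles[-1].append(s)
    ref_keys = [_window_key(s) for s in cycles[0]]
    for c, cyc in enumerate(cycles):
        keys = [_window_key(s) for s in cyc]
        if keys != ref_keys:
            raise StructureError(
                f"cycle {c} has isolation-window set {keys[1:]}, "
                f"expected {ref_keys[1:]}"
            )

    # --- name windows: ms1, then ms2-001.. by ascending precursor centre
    ms2_keys = ref_keys[1:]
    centers = {}
    for s in cycles[0][1:]:
        k = _window_key(s)
        centers[k] = (
            s.precursor_center
            if s.precursor_center is not None
            else 0.5 * (s.precursor_lower + s.precursor_upper)
        )
    ordered_ms2 = sorted(ms2_keys, key=lambda k: centers[k])
    names = {None: "ms1"}
    names.update({k: f"ms2-{j + 1:03d}" for j, k in enumerate(ordered_ms2)})

    windows = []
    for key in [None] + ordered_ms2:
        pos = ref_keys.index(key)
        scans = [cyc[pos] for cyc in cycles]
        windows.append(
            _import_window(names[key], key, scans, centers, tolerance_ppm)
        )
    run = RunModel(windows=windows, metadataXML=_build_metadata_xml(windows))
    run.validate()
    return run


def _import_window(name, key, scans, centers, tolerance_ppm) -> WindowMap:
    rts = np.array([s.retention_time for s in scans], dtype=np.float64)
    if len(rts) > 1:
        cycle_time = float(np.median(np.diff(rts)))
        if cycle_time <= 0:
            raise StructureError(f"window {name}: retention times not increasing")
        model = rts[0] + np.arange(len(rts)) * cycle_time
        jitter = np.max(np.abs(rts - model))
        if jitter > 0.1 * cycle_time:
            warnings.warn(
                f"window {name}: retention-time jitter {jitter:.4g}s exceeds 10% of "
                f"the cycle time; the uniform model is stored",
                stacklevel=3,
            )
    else:
        cycle_time = 1.0

    triplets = []
    alphas = np.empty(len(scans))
    betas = np.empty(len(scans))
    have = np.zeros(len(scans), dtype=bool)
    prev_params: IMSParams | None = None
    for si, s in enumerate(scans):
        nz = s.intensity > 0
        mz = s.mz[nz]
        inten = s.intensity[nz]
        if mz.size == 0:
            continue
        try:
            est = estimate_scan_ims(mz, seed_params=prev_params, tolerance_ppm=tolerance_ppm)
        except LossyInputError:
            raise
        except Exception as exc:
            resid = getattr(exc, "max_residual_ppm", float("nan"))
            raise LossyInputError(
                f"window {name}, scan {si}: m/z values cannot be placed on an "
                f"integer lattice within {tolerance_ppm} ppm (worst residual "
                f"{resid:.3g} ppm); profile TOF data is required",
                resid,
            ) from exc
        prev_params = est.params
        alphas[si], betas[si] = est.params.alpha, est.params.beta
        have[si] = True
        counts = round_half_away(inten)
        if np.any(np.abs(inten - counts) > 1e-6):
            warnings.warn(
                f"window {name}, scan {si}: non-integral profile intensities "
                f"rounded to counts",
                stacklevel=3,
            )
        keep = counts > 0
        for c, v in zip(est.indices[keep], counts[keep]):
            triplets.append((si, int(c), int(v)))

    if have.any():
        # fill empty scans with the nearest estimated coefficients
        idx = np.where(have)[0]
        for si in range(len(scans)):
            if not have[si]:
                j = idx[np.argmin(np.abs(idx - si))]
                alphas[si], betas[si] = alphas[j], betas[j]
    else:
        alphas[:], betas[:] = 1.0, 0.0

    if key is None:
        lower = center = upper = -1.0
    else:
        lower, upper = key
        center = centers[key]
    header = WindowHeader(
        name=name,
        precursorLower=float(lower),
        precursorCenter=float(center),
        precursorUpper=float(upper),
        firstScanRetentionTimeOffset=float(rts[0]),
        scanCycleTime=cycle_time,
        medianAlpha=float(np.median(alphas)),
        medianBeta=float(np.median(betas)),
        gamma=0,
        alphaPerScan=alphas,
        betaPerScan=betas,
    )
    return WindowMap(header=header, csr=build_csr(triplets, n_scans=len(scans)))


def export_run(run: RunModel) -> list[SpectrumRecord]:
    """Reconstruct the spectrum list, interleaved in cycle order.

    Within each cycle the MS1 spectrum precedes the MS2 spectra (in window
    order); across cycles spectra are sorted by retention time.
    """
    ordered = [run.ms1] + run.ms2_windows()
    n_scans = {w.n_scans for w in ordered}
    if len(n_scans) != 1:
        raise StructureError("all windows must have the same number of scans to export")
    (n,) = n_scans
    out: list[SpectrumRecord] = []
    for si in range(n):
        for w in ordered:
            h = w.header
            coords, inten = slice_scan(w.csr, si)
            alpha = h.alphaPerScan[si]
            beta = h.betaPerScan[si]
            mz = np.square(alpha * (coords.astype(np.float64) + h.gamma) + beta)
            rt = h.firstScanRetentionTimeOffset + si * h.scanCycleTime
            if h.is_ms1:
                out.append(SpectrumRecord(1, rt, mz, inten.astype(np.float64)))
            else:
                out.append(
                    SpectrumRecord(
                        2,
                        rt,
                        mz,
                        inten.astype(np.float64),
                        precursor_lower=h.precursorLower,
                        precursor_center=h.precursorCenter,
                        precursor_upper=h.precursorUpper,
                    )
                )
    return out


def _build_metadata_xml(windows) -> str:
    """A deterministic mzML-style header recording software and window layout."""
    root = etree.Element("runMetadata")
    sw = etree.SubElement(root, "software")
    sw.set("id", "toffee-py")
    il = etree.SubElement(root, "isolationWindowList")
    il.set("count", str(sum(1 for w in windows if not w.header.is_ms1)))
    for w in windows:
        if w.header.is_ms1:
            continue
        e = etree.SubElement(il, "isolationWindow")
        e.set("name", w.name)
        e.set("lower", repr(w.header.precursorLower))
        e.set("center", repr(w.header.precursorCenter))
        e.set("upper", repr(w.header.precursorUpper))
    return etree.tostring(root, encoding="unicode")


# ---------------------------------------------------------------------------
# mzML file I/O


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(bda) -> tuple[str | None, np.ndarray]:
    """Decode one binaryDataArray element (64/32-bit float, zlib or none)."""
    dtype = np.float64
    compressed = False
    kind = None
    text = ""
    for child in bda:
        name = _local(child.tag)
        if name == "cvParam":
            acc = child.get("accession")
            if acc == "MS:1000521":
                dtype = np.float32
            elif acc == "MS:1000523":
                dtype = np.float64
            elif acc == "MS:1000574":
                compressed = True
            elif acc == "MS:1000514":
                kind = "mz"
            elif acc == "MS:1000515":
                kind = "intensity"
        elif name == "binary":
            text = child.text or ""
    payload = base64.b64decode(text)
    if compressed:
        payload = zlib.decompress(payload)
    return kind, np.frombuffer(payload, dtype=dtype).astype(np.float64)


def read_mzml(path) -> list[SpectrumRecord]:
    """Read profile spectra from a (plain or indexed) mzML 1.1 file.

    Handles 32/64-bit float binary arrays with or without zlib compression,
    scan start times in seconds or minutes, and standard isolation-window
    CV parameters.
    """
    records = []
    for _event, elem in etree.iterparse(str(path), events=("end",)):
        if _local(elem.tag) != "spectrum":
            continue
        ms_level = 1
        rt = 0.0
        lower = center = upper = None
        lo_off = hi_off = 0.0
        mz = inten = None
        for node in elem.iter():
            name = _local(node.tag)
            if name == "cvParam":
                acc = node.get("accession")
                val = node.get("value")
                if acc == "MS:1000511":
                    ms_level = int(val)
                elif acc == "MS:1000016":
                    rt = float(val)
                    if node.get("unitName") == "minute":
                        rt *= 60.0
                elif acc == "MS:1000827":
                    center = float(val)
                elif acc == "MS:1000828":
                    lo_off = float(val)
                elif acc == "MS:1000829":
                    hi_off = float(val)
            elif name == "binaryDataArray":
                kind, arr = _decode_binary_array(node)
                if kind == "mz":
                    mz = arr
                elif kind == "intensity":
                    inten = arr
        if mz is None or inten is None:
            raise StructureError("spectrum without m/z or intensity array")
        if ms_level >= 2 and center is not None:
            lower, upper = center - lo_off, center + hi_off
        records.append(
            SpectrumRecord(
                ms_level=ms_level,
                retention_time=rt,
                mz=mz,
                intensity=inten,
                precursor_lower=lower,
                precursor_center=center,
                precursor_upper=upper,
            )
        )
        elem.clear(keep_tail=True)
    return records


_NS = "http://psi.hupo.org/ms/mzml"


def _cv(parent, accession, name, value="", unit=None):
    e = etree.SubElement(parent, "cvParam")
    e.set("cvRef", "MS")
    e.set("accession", accession)
    e.set("name", name)
    e.set("value", str(value))
    if unit is not None:
        u_acc, u_name, u_ref = unit
        e.set("unitCvRef", u_ref)
        e.set("unitAccession", u_acc)
        e.set("unitName", u_name)
    return e


def _binary_array(parent, data: np.ndarray, kind: str):
    payload = zlib.compress(np.asarray(data, dtype=np.float64).tobytes())
    bda = etree.SubElement(parent, "binaryDataArray")
    bda.set("encodedLength", str(len(base64.b64encode(payload))))
    _cv(bda, "MS:1000523", "64-bit float")
    _cv(bda, "MS:1000574", "zlib compression")
    if kind == "mz":
        _cv(bda, "MS:1000514", "m/z array", unit=("MS:1000040", "m/z", "MS"))
    else:
        _cv(
            bda,
            "MS:1000515",
            "intensity array",
            unit=("MS:1000131", "number of detector counts", "MS"),
        )
    b = etree.SubElement(bda, "binary")
    b.text = base64.b64encode(payload).decode("ascii")
    return bda


def write_mzml(spectra, path) -> None:
    """Write profile spectra as a minimal (plain, unindexed) mzML 1.1 document.

    Both binary arrays are stored as zlib-compressed 64-bit floats so that
    integer intensities up to 2**53 round-trip exactly.
    """
    spectra = list(spectra)
    root = etree.Element("mzML", nsmap={None: _NS})
    root.set("version", "1.1.0")
    cvlist = etree.SubElement(root, "cvList")
    cvlist.set("count", "2")
    for cid, name, uri in (
        ("MS", "Proteomics Standards Initiative Mass Spectrometry Ontology",
         "https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"),
        ("UO", "Unit Ontology",
         "https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"),
    ):
        cv = etree.SubElement(cvlist, "cv")
        cv.set("id", cid)
        cv.set("fullName", name)
        cv.set("URI", uri)

    fdl = etree.SubElement(root, "fileDescription")
    fc = etree.SubElement(fdl, "fileContent")
    _cv(fc, "MS:1000579", "MS1 spectrum")
    _cv(fc, "MS:1000580", "MSn spectrum")

    swl = etree.SubElement(root, "softwareList")
    swl.set("count", "1")
    sw = etree.SubElement(swl, "software")
    sw.set("id", "toffee-py")
    sw.set("version", "0.1.0")

    icl = etree.SubElement(root, "instrumentConfigurationList")
    icl.set("count", "1")
    ic = etree.SubElement(icl, "instrumentConfiguration")
    ic.set("id", "IC1")
    _cv(ic, "MS:1000084", "time-of-flight")

    dpl = etree.SubElement(root, "dataProcessingList")
    dpl.set("count", "1")
    dp = etree.SubElement(dpl, "dataProcessing")
    dp.set("id", "DP1")
    pm = etree.SubElement(dp, "processingMethod")
    pm.set("order", "0")
    pm.set("softwareRef", "toffee-py")
    _cv(pm, "MS:1000544", "Conversion to mzML")

    runel = etree.SubElement(root, "run")
    runel.set("id", "run1")
    runel.set("defaultInstrumentConfigurationRef", "IC1")
    sl = etree.SubElement(runel, "spectrumList")
    sl.set("count", str(len(spectra)))
    sl.set("defaultDataProcessingRef", "DP1")
    for i, s in enumerate(spectra):
        sp = etree.SubElement(sl, "spectrum")
        sp.set("index", str(i))
        sp.set("id", f"scan={i + 1}")
        sp.set("defaultArrayLength", str(s.mz.size))
        _cv(sp, "MS:1000511", "ms level", s.ms_level)
        _cv(sp, "MS:1000579" if s.ms_level == 1 else "MS:1000580",
            "MS1 spectrum" if s.ms_level == 1 else "MSn spectrum")
        _cv(sp, "MS:1000128", "profile spectrum")
        scl = etree.SubElement(sp, "scanList")
        scl.set("count", "1")
        _cv(scl, "MS:1000795", "no combination")
        sc = etree.SubElement(scl, "scan")
        _cv(sc, "MS:1000016", "scan start time", repr(float(s.retention_time)),
            unit=("UO:0000010", "second", "UO"))
        if s.ms_level >= 2:
            pl = etree.SubElement(sp, "precursorList")
            pl.set("count", "1")
            pr = etree.SubElement(pl, "precursor")
            iw = etree.SubElement(pr, "isolationWindow")
            center = (
                s.precursor_center
                if s.precursor_center is not None
                else 0.5 * (s.precursor_lower + s.precursor_upper)
            )
            _cv(iw, "MS:1000827", "isolation window target m/z", repr(float(center)),
                unit=("MS:1000040", "m/z", "MS"))
            _cv(iw, "MS:1000828", "isolation window lower offset",
                repr(float(center - s.precursor_lower)), unit=("MS:1000040", "m/z", "MS"))
            _cv(iw, "MS:1000829", "isolation window upper offset",
                repr(float(s.precursor_upper - center)), unit=("MS:1000040", "m/z", "MS"))
        bdal = etree.SubElement(sp, "binaryDataArrayList")
        bdal.set("count", "2")
        _binary_array(bdal, s.mz, "mz")
        _binary_array(bdal, s.intensity, "intensity")

    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)
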