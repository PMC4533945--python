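"""Reading and writing LC-MS/MS runs; uniform in-memory spectrum model.

MS1 and MS/MS scans are held as :class:`Spectrum` (centroided peak
lists), an RT-ordered sequence of which forms a :class:`Run`. MGF
(MS/MS-only) goes through pyteomics; mzML through a streaming lxml
reader (32/64-bit float arrays, optional zlib compression, indexed or
not) and a minimal writer (uncompressed 64-bit little-endian). RTs are
normalized to minutes regardless of file dialect.
"""

from __future__ import annotations

import base64
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree
from pyteomics import mgf as _mgf

__all__ = ["Spectrum", "Run", "read_run", "write_run", "select_ms2"]

_MZML_NS = "http://psi.hupo.org/ms/mzml"


@dataclass
class Spectrum:
    """One centroided scan.

    ``precursor_charge`` is ``None`` when the file did not record it
    (common in MGF); such scans are excluded from charge-filtered
    selection unless explicitly accepted.
    """

    ms_level: int
    rt: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float | None = None
    precursor_charge: int | None = None
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError(
                f"scan {self.scan_id!r}: m/z and intensity lengths differ "
                f"({self.mz.size} vs {self.intensity.size})"
            )
        if self.rt < 0:
            raise ValueError(f"scan {self.scan_id!r}: negative retention time")
        if self.mz.size > 1 and np.any(np.diff(self.mz) <= 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]


@dataclass
class Run:
    """An RT-ordered list of spectra plus source metadata."""

    spectra: list[Spectrum] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rts = [s.rt for s in self.spectra]
        if any(b < a for a, b in zip(rts, rts[1:])):
            warnings.warn("spectra not RT-ordered; sorting", stacklevel=2)
            self.spectra = sorted(self.spectra, key=lambda s: s.rt)

    def ms1(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 1]

    def ms2(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 2]

    def __len__(self) -> int:
        return len(self.spectra)


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt:
        return fmt.lower()
    suffix = Path(path).suffix.lower()
    if suffix == ".mzml":
        return "mzml"
    if suffix == ".mgf":
        return "mgf"
    raise ValueError(f"cannot infer run format from {path!r}; pass format=")


def read_run(path: str | Path, format: str | None = None) -> Run:
    """Load an mzML or MGF file into a :class:`Run`.

    MGF yields MS/MS scans only. Scans missing precursor charge are
    loaded with ``precursor_charge=None``. An empty file is an error.
    """
    fmt = _infer_format(path, format)
    path = str(path)
    spectra: list[Spectrum] = []
    if fmt == "mzml":
        for i, el in enumerate(_iter_mzml_spectra(path)):
            spectra.append(_spectrum_from_mzml(el, i))
    elif fmt == "mgf":
        with _mgf.read(path) as reader:
            for i, rec in enumerate(reader):
                spectra.append(_spectrum_from_mgf(rec, i))
    else:
        raise ValueError(f"unsupported run format {fmt!r}")
    if not spectra:
        raise ValueError(f"{path}: no spectra found")
    return Run(spectra=spectra, metadata={"source": path, "format": fmt})


def _iter_mzml_spectra(path: str):
    """Stream <spectrum> elements from an mzML file, freeing as we go."""
    try:
        context = etree.iterparse(
            path, events=("end",), tag=f"{{{_MZML_NS}}}spectrum"
        )
        for _event, el in context:
            yield el
            el.clear()
            while el.getprevious() is not None:
                del el.getparent()[0]
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"{path}: malformed mzML: {exc}") from exc


def _cv_params(el) -> dict[str, str]:
    """accession -> value for all cvParam descendants of an element."""
    return {
        cv.get("accession"): cv.get("value", "")
        for cv in el.iter(f"{{{_MZML_NS}}}cvParam")
    }


def _decode_binary_array(arr_el) -> np.ndarray:
    import zlib

    params = _cv_params(arr_el)
    binary = arr_el.findtext(f"{{{_MZML_NS}}}binary") or ""
    raw = base64.b64decode(binary)
    if "MS:1000574" in params:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in params else "<f8"  # 32- vs 64-bit float
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _spectrum_from_mzml(el, index: int) -> Spectrum:
    scan_id = el.get("id", f"index={index}")
    try:
        params = _cv_params_shallow(el)
        ms_level = int(params["MS:1000511"])
        rt = 0.0
        scan_el = el.find(
            f"{{{_MZML_NS}}}scanList/{{{_MZML_NS}}}scan"
        )
        if scan_el is not None:
            for cv in scan_el.iter(f"{{{_MZML_NS}}}cvParam"):
                if cv.get("accession") == "MS:1000016":
                    rt = float(cv.get("value"))
                    if "second" in (cv.get("unitName") or "minute"):
                        rt /= 60.0
        prec_mz = prec_z = None
        sel = el.find(
            f"{{{_MZML_NS}}}precursorList/{{{_MZML_NS}}}precursor/"
            f"{{{_MZML_NS}}}selectedIonList/{{{_MZML_NS}}}selectedIon"
        )
        if sel is not None:
            sel_params = _cv_params(sel)
            if "MS:1000744" in sel_params:
                prec_mz = float(sel_params["MS:1000744"])
            if "MS:1000041" in sel_params:
                prec_z = int(sel_params["MS:1000041"])
        mz_arr = inten_arr = np.empty(0)
        for arr_el in el.iter(f"{{{_MZML_NS}}}binaryDataArray"):
            arr_params = _cv_params(arr_el)
            if "MS:1000514" in arr_params:
                mz_arr = _decode_binary_array(arr_el)
            elif "MS:1000515" in arr_params:
                inten_arr = _decode_binary_array(arr_el)
        return Spectrum(
            ms_level=ms_level,
            rt=rt,
            mz=mz_arr,
            intensity=inten_arr,
            precursor_mz=prec_mz,
            precursor_charge=prec_z,
            scan_id=str(scan_id),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"malformed mzML spectrum {scan_id!r}: {exc}") from exc


def _cv_params_shallow(spectrum_el) -> dict[str, str]:
    """cvParams that are direct children of <spectrum> (e.g. ms level)."""
    return {
        cv.get("accession"): cv.get("value", "")
        for cv in spectrum_el.findall(f"{{{_MZML_NS}}}cvParam")
    }


def _spectrum_from_mgf(rec: dict, index: int) -> Spectrum:
    params = rec.get("params", {})
    title = str(params.get("title", f"index={index}"))
    try:
        rt = params.get("rtinseconds")
        rt_min = float(rt) / 60.0 if rt is not None else 0.0
        pepmass = params.get("pepmass")
        prec_mz = float(pepmass[0]) if pepmass else None
        charge = params.get("charge")
        prec_z = int(charge[0]) if charge else None
        return Spectrum(
            ms_level=2,
            rt=rt_min,
            mz=rec["m/z array"],
            intensity=rec["intensity array"],
            precursor_mz=prec_mz,
            precursor_charge=prec_z,
            scan_id=title,
        )
    except (KeyError, TypeError, ValueError, IndexError) as exc:
        raise ValueError(f"malformed MGF spectrum {title!r}: {exc}") from exc


def select_ms2(
    run: Run,
    target_mz: float,
    charge: int | None = None,
    iso_window: float = 2.0,
    accept_unknown_charge: bool = False,
) -> list[Spectrum]:
    """MS/MS scans whose precursor falls in the isolation window.

    ``iso_window`` is the full window width in Th (a 2.00 window accepts
    |precursor - target| <= 1.00). Charge must match when given; scans
    with unknown charge pass only with ``accept_unknown_charge``.
    Ordering of the run is preserved.
    """
    if iso_window <= 0:
        raise ValueError("iso_window must be positive")
    half = iso_window / 2.0
    out = []
    for s in run.ms2():
        if s.precursor_mz is None or abs(s.precursor_mz - target_mz) > half:
            continue
        if charge is not None:
            if s.precursor_charge is None:
                if not accept_unknown_charge:
                    continue
            elif s.precursor_charge != charge:
                continue
        out.append(s)
    return out


# ---------------------------------------------------------------- writers


def write_run(run: Run, path: str | Path, format: str | None = None) -> None:
    """Write a run as mzML or MGF (MGF keeps MS/MS scans only)."""
    fmt = _infer_format(path, format)
    if fmt == "mzml":
        _write_mzml(run, str(path))
    elif fmt == "mgf":
        _write_mgf(run, str(path))
    else:
        raise ValueError(f"unsupported run format {fmt!r}")


def _write_mgf(run: Run, path: str) -> None:
    records = []
    for s in run.ms2():
        params = {
            "title": s.scan_id,
            "rtinseconds": round(s.rt * 60.0, 6),
        }
        if s.precursor_mz is not None:
            params["pepmass"] = s.precursor_mz
        if s.precursor_charge is not None:
            params["charge"] = s.precursor_charge
        records.append(
            {"m/z array": s.mz, "intensity array": s.intensity, "params": params}
        )
    _mgf.write(records, output=path, file_mode="w")


def _cv(parent, accession: str, name: str, value: str = "", **extra) -> None:
    attrs = {"cvRef": "MS", "accession": accession, "name": name, "value": value}
    attrs.update(extra)
    etree.SubElement(parent, f"{{{_MZML_NS}}}cvParam", attrs)


def _binary_array(parent, values: np.ndarray, accession: str, name: str) -> None:
    raw = struct.pack(f"<{values.size}d", *map(float, values))
    b64 = base64.b64encode(raw).decode("ascii")
    arr = etree.SubElement(
        parent,
        f"{{{_MZML_NS}}}binaryDataArray",
        {"encodedLength": str(len(b64))},
    )
    _cv(arr, "MS:1000523", "64-bit float")
    _cv(arr, "MS:1000576", "no compression")
    _cv(arr, accession, name)
    etree.SubElement(arr, f"{{{_MZML_NS}}}binary").text = b64


def _write_mzml(run: Run, path: str) -> None:
    nsmap = {None: _MZML_NS}
    root = etree.Element(
        f"{{{_MZML_NS}}}mzML", {"version": "1.1.0"}, nsmap=nsmap
    )
    cv_list = etree.SubElement(root, f"{{{_MZML_NS}}}cvList", {"count": "2"})
    etree.SubElement(
        cv_list,
        f"{{{_MZML_NS}}}cv",
        {"id": "MS", "fullName": "PSI-MS", "URI": "https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"},
    )
    etree.SubElement(
        cv_list,
        f"{{{_MZML_NS}}}cv",
        {"id": "UO", "fullName": "Unit Ontology", "URI": "https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"},
    )
    run_el = etree.SubElement(
        root, f"{{{_MZML_NS}}}run", {"id": str(run.metadata.get("id", "run"))}
    )
    slist = etree.SubElement(
        run_el, f"{{{_MZML_NS}}}spectrumList", {"count": str(len(run.spectra))}
    )
    for i, s in enumerate(run.spectra):
        sp = etree.SubElement(
            slist,
            f"{{{_MZML_NS}}}spectrum",
            {
                "index": str(i),
                "id": s.scan_id or f"scan={i + 1}",
                "defaultArrayLength": str(s.mz.size),
            },
        )
        _cv(sp, "MS:1000511", "ms level", str(s.ms_level))
        _cv(sp, "MS:1000127", "centroid spectrum")
        if s.ms_level == 1:
            _cv(sp, "MS:1000579", "MS1 spectrum")
        else:
            _cv(sp, "MS:1000580", "MSn spectrum")
        scan_list = etree.SubElement(
            sp, f"{{{_MZML_NS}}}scanList", {"count": "1"}
        )
        _cv(scan_list, "MS:1000795", "no combination")
        scan = etree.SubElement(scan_list, f"{{{_MZML_NS}}}scan")
        _cv(
            scan,
            "MS:1000016",
            "scan start time",
            repr(round(s.rt, 8)),
            unitCvRef="UO",
            unitAccession="UO:0000031",
            unitName="minute",
        )
        if s.ms_level == 2 and s.precursor_mz is not None:
            plist = etree.SubElement(
                sp, f"{{{_MZML_NS}}}precursorList", {"count": "1"}
            )
            prec = etree.SubElement(plist, f"{{{_MZML_NS}}}precursor")
            sil = etree.SubElement(
                prec, f"{{{_MZML_NS}}}selectedIonList", {"count": "1"}
            )
            sel = etree.SubElement(sil, f"{{{_MZML_NS}}}selectedIon")
            _cv(sel, "MS:1000744", "selected ion m/z", repr(s.precursor_mz))
            if s.precursor_charge is not None:
                _cv(sel, "MS:1000041", "charge state", str(s.precursor_charge))
            act = etree.SubElement(prec, f"{{{_MZML_NS}}}activation")
            _cv(act, "MS:1000133", "collision-induced dissociation")
        arrays = etree.SubElement(
            sp, f"{{{_MZML_NS}}}binaryDataArrayList", {"count": "2"}
        )
        _binary_array(arrays, s.mz, "MS:1000514", "m/z array")
        _binary_array(arrays, s.intensity, "MS:1000515", "intensity array")
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)
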