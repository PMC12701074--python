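"""Centroided MS run I/O with MS1 -> MS2 -> MS3 lineage (MGF and mzML).

MGF has no native scan lineage, so it is encoded in the TITLE field with the
grammar ``scan=<n> level=<l> [parent=<m> selected_mz=<x>] [activation=<a>]``;
the reader recovers it.  mzML lineage uses the native precursorList
``spectrumRef`` attributes.  Only centroided spectra are handled.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import base64
import struct
import zlib

import numpy as np
from pyteomics import mgf as _mgf


@dataclass
class Spectrum:
    """One centroided scan.

    ``peaks`` are kept strictly sorted ascending by m/z.  Levels 2-3 carry a
    precursor m/z and charge (charge 0 = undetermined); level 3 additionally
    carries the parent MS2 scan id and the selected fragment m/z.
    """

    scan_id: int
    ms_level: int
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float | None = None
    precursor_charge: int = 0
    parent_scan: int | None = None
    selected_mz: float | None = None
    activation: str | None = None
    orphan: bool = False

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if self.mz.size and not np.all(np.diff(self.mz) > 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if np.any(self.mz <= 0) or np.any(self.intensity < 0):
            raise ValueError("peak m/z must be positive and intensity non-negative")

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


@dataclass
class Run:
    """An ordered collection of spectra with unique scan ids."""

    spectra: list[Spectrum] = field(default_factory=list)
    source: str = ""
    linker: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        ids = [s.scan_id for s in self.spectra]
        if len(ids) != len(set(ids)):
            raise ValueError("scan ids must be unique within a run")
        self._by_id = {s.scan_id: s for s in self.spectra}

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __len__(self) -> int:
        return len(self.spectra)

    def __getitem__(self, scan_id: int) -> Spectrum:
        return self._by_id[scan_id]

    def by_level(self, level: int) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == level]

    def children_of(self, scan_id: int) -> list[Spectrum]:
        return [s for s in self.spectra if s.parent_scan == scan_id]


_TITLE_RE = re.compile(
    r"scan=(?P<scan>\d+)\s+level=(?P<level>\d)"
    r"(?:\s+parent=(?P<parent>\d+)\s+selected_mz=(?P<sel>[\d.]+))?"
    r"(?:\s+activation=(?P<act>\S+))?"
)


def _resolve_lineage(spectra: list[Spectrum]) -> None:
    known = {s.scan_id for s in spectra}
    for s in spectra:
        if s.ms_level == 3 and (s.parent_scan is None or s.parent_scan not in known):
            warnings.warn(
                f"MS3 scan {s.scan_id} has no resolvable parent MS2 scan",
                stacklevel=3,
            )
            s.orphan = True


def _read_mgf(path: Path) -> list[Spectrum]:
    spectra: list[Spectrum] = []
    with _mgf.MGF(str(path)) as reader:
        for i, rec in enumerate(reader):
            params = rec["params"]
            title = str(params.get("title", ""))
            m = _TITLE_RE.search(title)
            if m:
                scan_id = int(m.group("scan"))
                level = int(m.group("level"))
                parent = int(m.group("parent")) if m.group("parent") else None
                selected = float(m.group("sel")) if m.group("sel") else None
                activation = m.group("act")
            else:
                scan_id, level, parent, selected, activation = i + 1, 2, None, None, None
            pepmass = params.get("pepmass")
            prec_mz = float(pepmass[0]) if pepmass else None
            charge_field = params.get("charge")
            charge = int(charge_field[0]) if charge_field else 0
            spectra.append(
                Spectrum(
                    scan_id=scan_id,
                    ms_level=level,
                    mz=rec["m/z array"],
                    intensity=rec["intensity array"],
                    precursor_mz=prec_mz,
                    precursor_charge=charge,
                    parent_scan=parent,
                    selected_mz=selected,
                    activation=activation,
                )
            )
    return spectra


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"

# CV accessions for the mzML subset handled here (centroided spectra with
# precursor lineage; 32/64-bit float arrays, zlib or no compression).
_ACC_MS_LEVEL = "MS:1000511"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_CHARGE = "MS:1000041"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INTENSITY_ARRAY = "MS:1000515"
_ACC_64BIT = "MS:1000523"
_ACC_32BIT = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_HCD = "MS:1000422"
_ACC_CID = "MS:1000133"


def _decode_binary_array(elem) -> np.ndarray:
    accs = {cv.get("accession") for cv in elem.iter(_MZML_NS + "cvParam")}
    node = elem.find(_MZML_NS + "binary")
    raw = base64.b64decode((node.text or "").strip()) if node is not None else b""
    if _ACC_ZLIB in accs:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_32BIT in accs and _ACC_64BIT not in accs else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: Path) -> list[Spectrum]:
    from lxml import etree

    scan_re = re.compile(r"scan=(\d+)")

    def scan_number(id_string: str, fallback: int) -> int:
        m = scan_re.search(id_string or "")
        return int(m.group(1)) if m else fallback

    spectra: list[Spectrum] = []
    for i, (_, elem) in enumerate(
        etree.iterparse(str(path), events=("end",), tag=_MZML_NS + "spectrum")
    ):
        level = 1
        for cv in elem.findall(_MZML_NS + "cvParam"):
            if cv.get("accession") == _ACC_MS_LEVEL:
                level = int(cv.get("value"))
        scan_id = scan_number(elem.get("id", ""), i + 1)

        prec_mz = None
        charge = 0
        parent = None
        selected = None
        activation = None
        prec = elem.find(f"{_MZML_NS}precursorList/{_MZML_NS}precursor")
        if prec is not None:
            ref = prec.get("spectrumRef")
            if ref:
                parent = scan_number(ref, -1)
            for cv in prec.iter(_MZML_NS + "cvParam"):
                acc = cv.get("accession")
                if acc == _ACC_SELECTED_MZ:
                    prec_mz = float(cv.get("value"))
                elif acc == _ACC_CHARGE:
                    charge = int(float(cv.get("value")))
                elif acc == _ACC_HCD:
                    activation = "HCD"
                elif acc == _ACC_CID and activation is None:
                    activation = "CID"
            if level == 3:
                selected = prec_mz

        mz = np.array([])
        intensity = np.array([])
        for arr in elem.iter(_MZML_NS + "binaryDataArray"):
            accs = {cv.get("accession") for cv in arr.iter(_MZML_NS + "cvParam")}
            if _ACC_MZ_ARRAY in accs:
                mz = _decode_binary_array(arr)
            elif _ACC_INTENSITY_ARRAY in accs:
                intensity = _decode_binary_array(arr)
        spectra.append(
            Spectrum(
                scan_id=scan_id,
                ms_level=level,
                mz=mz,
                intensity=intensity,
                precursor_mz=prec_mz,
                precursor_charge=charge,
                parent_scan=parent if level >= 3 else None,
                selected_mz=selected,
                activation=activation,
            )
        )
        elem.clear()
    return spectra


def read_run(path: str | Path, format: str | None = None, **metadata: str) -> Run:
    """Read an MS run from MGF or mzML; format inferred from the extension.

    MS3 scans whose parent MS2 is missing are kept but flagged ``orphan``
    (with a warning).  An empty or unparsable file raises ``ValueError``.
    """
    path = Path(path)
    if format is None:
        format = "mzml" if path.suffix.lower() == ".mzml" else "mgf"
    if format not in ("mgf", "mzml"):
        raise ValueError(f"unknown format {format!r}")
    try:
        spectra = _read_mgf(path) if format == "mgf" else _read_mzml(path)
    except (OSError, ValueError):
        raise
    except Exception as exc:
        raise ValueError(f"malformed {format} file {path}: {exc}") from exc
    if not spectra:
        raise ValueError(f"no spectra found in {path}")
    _resolve_lineage(spectra)
    return Run(spectra=spectra, source=str(path), **metadata)


def write_mgf(run: Run, path: str | Path) -> None:
    """Write a run as MGF with lineage encoded in TITLE (see module docstring).

    MS1 spectra are written without PEPMASS/CHARGE.  The round trip
    ``read_run(write_mgf(run))`` reproduces m/z to 1e-4 and intensities to
    1e-3 relative.
    """
    records = []
    for s in run.spectra:
        title = f"scan={s.scan_id} level={s.ms_level}"
        if s.parent_scan is not None and s.selected_mz is not None:
            title += f" parent={s.parent_scan} selected_mz={s.selected_mz:.5f}"
        if s.activation:
            title += f" activation={s.activation}"
        params: dict = {"title": title}
        if s.precursor_mz is not None:
            params["pepmass"] = s.precursor_mz
        if s.precursor_charge:
            params["charge"] = s.precursor_charge
        records.append(
            {"params": params, "m/z array": s.mz, "intensity array": s.intensity}
        )
    with open(path, "w") as fh:
        _mgf.write(records, fh)


def select_precursors(run: Run, charge_range: tuple[int, int] = (4, 8)) -> list[Spectrum]:
    """MS2 spectra whose precursor charge lies in ``charge_range`` (inclusive).

    The default 4+ to 8+ window mirrors the acquisition used for cross-linked
    peptides; undetermined charge (0) is always excluded.
    """
    lo, hi = charge_range
    return [
        s
        for s in run.by_level(2)
        if s.precursor_charge and lo <= s.precursor_charge <= hi
    ]
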