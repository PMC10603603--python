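"""Spectrum domain types and peak-list I/O (mzML, MGF, MS3 target TSV).

Spectra are centroided peak lists.  Precursor charge may be absent in real
files; it is encoded as 0 ("unknown") and such spectra still flow through the
pipeline (the second-peptide-mass filter, which needs a precursor neutral
mass, is then skipped and the decision flagged).
"""

from __future__ import annotations

import base64
import csv
import logging
import struct
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from pyteomics import mgf as _mgf

from .chem import PROTON_MASS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("peak m/z must be positive")
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")


@dataclass(frozen=True)
class PrecursorInfo:
    """Isolated-ion descriptor. charge 0 means charge unknown."""

    mz: float
    charge: int

    @property
    def neutral_mass(self) -> float | None:
        """Neutral mass in Da, or None when the charge is unknown."""
        if self.charge <= 0:
            return None
        return (self.mz - PROTON_MASS) * self.charge


@dataclass
class Spectrum:
    """One centroided scan; peaks are kept strictly sorted by m/z."""

    scan_id: str
    ms_level: int
    peaks: list[Peak]
    precursor: PrecursorInfo

    def __post_init__(self) -> None:
        if self.ms_level not in (2, 3):
            raise ValueError("ms_level must be 2 or 3")
        mzs = [p.mz for p in self.peaks]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            self.peaks = sorted(self.peaks, key=lambda p: p.mz)

    @property
    def total_intensity(self) -> float:
        return sum(p.intensity for p in self.peaks)


# ---------------------------------------------------------------------------
# Reading


def _charge_from(value) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        return 0


def _read_mgf(path: str | Path) -> Iterator[Spectrum]:
    with _mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            pepmass = params.get("pepmass")
            if pepmass is None:
                logger.warning("MGF block %d has no PEPMASS; skipped", i)
                continue
            charge_field = params.get("charge")
            charge = _charge_from(charge_field[0]) if charge_field else 0
            scan_id = str(params.get("title", f"index={i}"))
            peaks = [
                Peak(float(mz), float(it))
                for mz, it in zip(entry["m/z array"], entry["intensity array"])
            ]
            yield Spectrum(
                scan_id=scan_id,
                ms_level=2,  # MGF carries no MS level; treated as MS2
                peaks=peaks,
                precursor=PrecursorInfo(mz=float(pepmass[0]), charge=charge),
            )


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"

# accession -> handling of binary arrays
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_64BIT = "MS:1000523"
_ACC_32BIT = "MS:1000521"
_ACC_ZLIB = "MS:1000574"


def _cv_params(element) -> dict[str, str]:
    return {
        cv.get("accession"): cv.get("value", "")
        for cv in element.iter(f"{_MZML_NS}cvParam")
    }


def _decode_binary_array(ba_element) -> tuple[str | None, list[float]]:
    """Decode one <binaryDataArray>; returns (kind, values) where kind is
    'mz', 'intensity' or None."""
    params = _cv_params(ba_element)
    kind = "mz" if _ACC_MZ_ARRAY in params else ("intensity" if _ACC_INT_ARRAY in params else None)
    binary = ba_element.find(f"{_MZML_NS}binary")
    if binary is None or not (binary.text or "").strip():
        return kind, []
    raw = base64.b64decode(binary.text.strip())
    if _ACC_ZLIB in params:
        import zlib

        raw = zlib.decompress(raw)
    width = "f" if _ACC_32BIT in params else "d"
    count = len(raw) // struct.calcsize(width)
    return kind, list(struct.unpack(f"<{count}{width}", raw))


def _read_mzml(path: str | Path) -> Iterator[Spectrum]:
    """Stream spectra from centroided mzML.

    A deliberately small reader for the PSI-mzML subset this package writes
    and that centroided converters emit: ms level, scan id, selected ion
    m/z + charge state, 32/64-bit (optionally zlib) peak arrays.  Written
    in-package because no installed library parses mzML here.
    """
    for _event, spec_el in ET.iterparse(str(path), events=("end",)):
        if spec_el.tag != f"{_MZML_NS}spectrum":
            continue
        params = _cv_params(spec_el)
        level = int(params.get("MS:1000511", 0) or 0)
        scan_id = spec_el.get("id", "")
        if level in (2, 3):
            ion = spec_el.find(
                f"{_MZML_NS}precursorList/{_MZML_NS}precursor/"
                f"{_MZML_NS}selectedIonList/{_MZML_NS}selectedIon"
            )
            if ion is None and level == 2:
                logger.warning("spectrum %s has no precursor; skipped", scan_id)
                spec_el.clear()
                continue
            ion_params = _cv_params(ion) if ion is not None else {}
            prec_mz = float(ion_params.get("MS:1000744", 0.0) or 0.0)
            charge = _charge_from(ion_params.get("MS:1000041"))
            arrays: dict[str, list[float]] = {}
            for ba in spec_el.iter(f"{_MZML_NS}binaryDataArray"):
                kind, values = _decode_binary_array(ba)
                if kind:
                    arrays[kind] = values
            peaks = [
                Peak(mz, it)
                for mz, it in zip(arrays.get("mz", []), arrays.get("intensity", []))
                if mz > 0
            ]
            yield Spectrum(
                scan_id=scan_id,
                ms_level=level,
                peaks=peaks,
                precursor=PrecursorInfo(mz=prec_mz, charge=charge),
            )
        spec_el.clear()


def read_spectra(path: str | Path, format: str = "auto") -> Iterator[Spectrum]:
    """Stream :class:`Spectrum` objects from an mzML or MGF file, in file order.

    ``format`` is one of ``mzml``, ``mgf``, ``auto`` (extension-based).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format == "auto":
        format = "mzml" if path.suffix.lower() == ".mzml" else "mgf"
    if format == "mgf":
        return _read_mgf(path)
    if format == "mzml":
        return _read_mzml(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Writing


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF (Matrix Science dialect)."""
    entries = []
    for s in spectra:
        params = {"title": s.scan_id, "pepmass": (s.precursor.mz, None)}
        if s.precursor.charge > 0:
            params["charge"] = [s.precursor.charge]
        entries.append(
            {
                "params": params,
                "m/z array": [p.mz for p in s.peaks],
                "intensity array": [p.intensity for p in s.peaks],
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def _b64_doubles(values: list[float]) -> str:
    return base64.b64encode(struct.pack(f"<{len(values)}d", *values)).decode()


def _cv(parent, accession: str, name: str, value: str = "") -> None:
    ET.SubElement(
        parent,
        "cvParam",
        cvRef="MS",
        accession=accession,
        name=name,
        value=value,
    )


def write_mzml(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write a minimal centroided mzML file (64-bit, uncompressed arrays).

    Covers the subset of PSI-mzML needed for round-tripping synthetic spectra:
    ms level, scan id, selected-ion m/z + charge, m/z and intensity arrays.
    """
    spectra = list(spectra)
    root = ET.Element(
        "mzML",
        xmlns="http://psi.hupo.org/ms/mzml",
        version="1.1.0",
    )
    cv_list = ET.SubElement(root, "cvList", count="1")
    ET.SubElement(
        cv_list,
        "cv",
        id="MS",
        fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    run = ET.SubElement(root, "run", id="synthetic")
    slist = ET.SubElement(run, "spectrumList", count=str(len(spectra)))
    for idx, s in enumerate(spectra):
        spec_el = ET.SubElement(
            slist,
            "spectrum",
            index=str(idx),
            id=s.scan_id,
            defaultArrayLength=str(len(s.peaks)),
        )
        _cv(spec_el, "MS:1000511", "ms level", str(s.ms_level))
        _cv(spec_el, "MS:1000127", "centroid spectrum")
        plist = ET.SubElement(spec_el, "precursorList", count="1")
        prec = ET.SubElement(plist, "precursor")
        ilist = ET.SubElement(prec, "selectedIonList", count="1")
        ion = ET.SubElement(ilist, "selectedIon")
        _cv(ion, "MS:1000744", "selected ion m/z", repr(s.precursor.mz))
        if s.precursor.charge > 0:
            _cv(ion, "MS:1000041", "charge state", str(s.precursor.charge))
        balist = ET.SubElement(spec_el, "binaryDataArrayList", count="2")
        for accession, name, values in (
            ("MS:1000514", "m/z array", [p.mz for p in s.peaks]),
            ("MS:1000515", "intensity array", [p.intensity for p in s.peaks]),
        ):
            encoded = _b64_doubles(values)
            ba = ET.SubElement(balist, "binaryDataArray", encodedLength=str(len(encoded)))
            _cv(ba, "MS:1000523", "64-bit float")
            _cv(ba, "MS:1000576", "no compression")
            _cv(ba, accession, name)
            ET.SubElement(ba, "binary").text = encoded
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(str(path), xml_declaration=True, encoding="utf-8")


def write_spectra(spectra: Iterable[Spectrum], path: str | Path, format: str = "auto") -> None:
    path = Path(path)
    if format == "auto":
        format = "mzml" if path.suffix.lower() == ".mzml" else "mgf"
    if format == "mgf":
        write_mgf(spectra, path)
    elif format == "mzml":
        write_mzml(spectra, path)
    else:
        raise ValueError(f"unknown format {format!r}")


MS3_TARGET_COLUMNS = (
    "scan_id",
    "target_mz",
    "target_charge",
    "doublet_rank",
    "second_peptide_mass",
)


def write_ms3_targets(decisions, path: str | Path, header_comment: str | None = None) -> None:
    """Write MS3 target lists as TSV, one row per target, in scan then
    selection order.  ``decisions`` is an iterable of
    :class:`~xltrigger.doublets.MS3Decision`."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(MS3_TARGET_COLUMNS)
        for decision in decisions:
            for target in decision.targets:
                spm = target.source.second_peptide_mass
                writer.writerow(
                    [
                        decision.scan_id,
                        f"{target.mz:.6f}",
                        target.charge,
                        target.source.doublet_rank,
                        "" if spm is None else f"{spm:.4f}",
                    ]
                )


def read_ms3_targets(path: str | Path) -> list[dict]:
    """Read a target TSV back as a list of row dicts (typed mz/charge)."""
    rows = []
    with open(path, newline="", encoding="utf-8") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    reader = csv.DictReader(lines, delimiter="\t")
    for row in reader:
        rows.append(
            {
                "scan_id": row["scan_id"],
                "target_mz": float(row["target_mz"]),
                "target_charge": int(row["target_charge"]),
                "doublet_rank": int(row["doublet_rank"]),
                "second_peptide_mass": (
                    float(row["second_peptide_mass"]) if row["second_peptide_mass"] else None
                ),
            }
        )
    return rows
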