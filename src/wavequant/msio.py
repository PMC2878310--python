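"""Reading and writing the MS file formats the pipeline touches.

* mzXML is read through :mod:`pyteomics.mzxml`.
* mzML is read and written by a compact codec in this module (lxml
  parsing, base64-encoded little-endian float arrays, zlib optional on
  read). The writer emits the minimal subset of mzML 1.1 — run /
  spectrumList / spectrum with scan start time and m/z + intensity
  binary arrays — which is enough for XIC extraction and keeps synthetic
  fixtures plain-text and round-trippable.
* Peptide target tables are tab-separated with a header:
  ``peptide  protein  charge  mz_light  mz_heavy  seed_scan``.

All readers yield uniform spectrum records ``(scan_number, rt_seconds,
mz_array, intensity_array)`` sorted as stored.
"""

from __future__ import annotations

import base64
import zlib
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from lxml import etree

from .errors import EmptyInputError

__all__ = ["read_spectra", "read_mzml", "read_mzxml", "write_mzml", "read_target_table"]

_NS = "http://psi.hupo.org/ms/mzml"

TARGET_COLUMNS = ["peptide", "protein", "charge", "mz_light", "mz_heavy", "seed_scan"]

# accessions the reader understands
_ACC_MZ = "MS:1000514"
_ACC_INTENSITY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_RT = "MS:1000016"


def _decode_binary_array(bda: etree._Element) -> np.ndarray:
    dtype = "<f8"
    compressed = False
    payload = None
    for cv in bda.iter(f"{{{_NS}}}cvParam"):
        acc = cv.get("accession")
        if acc == _ACC_F32:
            dtype = "<f4"
        elif acc == _ACC_ZLIB:
            compressed = True
    binary = bda.find(f"{{{_NS}}}binary")
    raw = base64.b64decode(binary.text or "")
    if compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path: str | Path) -> Iterator[tuple[int, float, np.ndarray, np.ndarray]]:
    """Yield (scan, rt_seconds, mz, intensity) from an mzML file."""
    n = 0
    for _, spectrum in etree.iterparse(str(path), tag=f"{{{_NS}}}spectrum"):
        scan = None
        sid = spectrum.get("id", "")
        for token in sid.split():
            if token.startswith("scan="):
                scan = int(token[5:])
        if scan is None:
            scan = int(spectrum.get("index", n)) + 1
        rt = 0.0
        for cv in spectrum.iter(f"{{{_NS}}}cvParam"):
            if cv.get("accession") == _ACC_RT:
                rt = float(cv.get("value"))
                if cv.get("unitName", "second").startswith("minute"):
                    rt *= 60.0
        mz = inten = None
        for bda in spectrum.iter(f"{{{_NS}}}binaryDataArray"):
            accs = {cv.get("accession") for cv in bda.iter(f"{{{_NS}}}cvParam")}
            if _ACC_MZ in accs:
                mz = _decode_binary_array(bda)
            elif _ACC_INTENSITY in accs:
                inten = _decode_binary_array(bda)
        spectrum.clear()
        if mz is None or inten is None:
            continue
        n += 1
        yield scan, rt, mz, inten
    if n == 0:
        raise EmptyInputError(f"no spectra found in {path}")


def read_mzxml(path: str | Path) -> Iterator[tuple[int, float, np.ndarray, np.ndarray]]:
    """Yield (scan, rt_seconds, mz, intensity) from an mzXML file."""
    from pyteomics import mzxml

    n = 0
    with mzxml.read(str(path)) as reader:
        for s in reader:
            rt = s.get("retentionTime", 0.0)
            # pyteomics returns a unitfloat, minutes by mzXML convention
            unit = getattr(rt, "unit_info", "minute")
            rt_s = float(rt) * 60.0 if str(unit).startswith("minute") else float(rt)
            n += 1
            yield int(s["num"]), rt_s, s["m/z array"], s["intensity array"]
    if n == 0:
        raise EmptyInputError(f"no spectra found in {path}")


def read_spectra(path: str | Path) -> Iterator[tuple[int, float, np.ndarray, np.ndarray]]:
    """Dispatch on file suffix: .mzML or .mzXML (case-insensitive)."""
    suffix = Path(path).suffix.lower()
    if suffix == ".mzml":
        return read_mzml(path)
    if suffix == ".mzxml":
        return read_mzxml(path)
    raise ValueError(f"unsupported spectra format {suffix!r} (expected .mzML or .mzXML)")


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode("ascii")


def write_mzml(spectra, path: str | Path) -> None:
    """Write (scan, rt_seconds, mz, intensity) records as minimal mzML.

    Arrays are stored as uncompressed base64 64-bit floats, so the file
    is plain text and the round trip through :func:`read_mzml` is exact.
    """
    spectra = list(spectra)
    root = etree.Element(f"{{{_NS}}}mzML", nsmap={None: _NS}, version="1.1.0")
    cvlist = etree.SubElement(root, f"{{{_NS}}}cvList", count="1")
    etree.SubElement(
        cvlist, f"{{{_NS}}}cv", id="MS", fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    run = etree.SubElement(root, f"{{{_NS}}}run", id="run1")
    slist = etree.SubElement(run, f"{{{_NS}}}spectrumList", count=str(len(spectra)))

    def cv(parent, accession, name, value="", **extra):
        etree.SubElement(
            parent, f"{{{_NS}}}cvParam", cvRef="MS", accession=accession, name=name,
            value=str(value), **extra,
        )

    for index, (scan, rt, mz, inten) in enumerate(spectra):
        sp = etree.SubElement(
            slist, f"{{{_NS}}}spectrum", index=str(index), id=f"scan={int(scan)}",
            defaultArrayLength=str(len(mz)),
        )
        cv(sp, "MS:1000511", "ms level", 1)
        cv(sp, "MS:1000127", "centroid spectrum")
        scanlist = etree.SubElement(sp, f"{{{_NS}}}scanList", count="1")
        scan_el = etree.SubElement(scanlist, f"{{{_NS}}}scan")
        cv(scan_el, _ACC_RT, "scan start time", repr(float(rt)),
           unitCvRef="UO", unitAccession="UO:0000010", unitName="second")
        balist = etree.SubElement(sp, f"{{{_NS}}}binaryDataArrayList", count="2")
        for arr, acc, name in ((mz, _ACC_MZ, "m/z array"), (inten, _ACC_INTENSITY, "intensity array")):
            enc = _b64(arr)
            bda = etree.SubElement(balist, f"{{{_NS}}}binaryDataArray", encodedLength=str(len(enc)))
            cv(bda, _ACC_F64, "64-bit float")
            cv(bda, "MS:1000576", "no compression")
            cv(bda, acc, name)
            etree.SubElement(bda, f"{{{_NS}}}binary").text = enc
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)


def read_target_table(path: str | Path) -> pd.DataFrame:
    """Read the tab-separated peptide target table, validating columns."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in TARGET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"target table {path} missing columns: {missing}")
    return df
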