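"""Minimal read-only mzML support (stdlib only).

Handles the common encodings: 32/64-bit float m/z and intensity arrays,
little-endian, base64, optionally zlib-compressed. Only single-spectrum
reads are supported; anything unusual raises a FormatError naming the scan.
"""

from __future__ import annotations

import base64
import struct
import xml.etree.ElementTree as ET
import zlib
from pathlib import Path

import numpy as np

_NS = "{http://psi.hupo.org/ms/mzml}"

# accession -> meaning for the binary-array cvParams we understand
_ACC_FLOAT64 = "MS:1000523"
_ACC_FLOAT32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NO_COMPRESSION = "MS:1000576"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INTENSITY_ARRAY = "MS:1000515"


def read_mzml_spectrum(path, index: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Return (mz, intensity) arrays for one spectrum of an mzML file."""
    from seldi_nodal.spectra_io import FormatError

    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise FormatError(f"{path}: not well-formed XML: {exc}") from exc

    spectra = tree.getroot().iter(f"{_NS}spectrum")
    spectrum = None
    for i, elem in enumerate(spectra):
        if i == index:
            spectrum = elem
            break
    if spectrum is None:
        raise FormatError(f"{path}: no spectrum at index {index}")
    scan_id = spectrum.get("id", f"index={index}")

    mz = intensity = None
    for bda in spectrum.iter(f"{_NS}binaryDataArray"):
        accessions = {cv.get("accession") for cv in bda.iter(f"{_NS}cvParam")}
        binary = bda.find(f"{_NS}binary")
        if binary is None or binary.text is None:
            raise FormatError(f"{path} scan {scan_id}: empty <binary> element")
        raw = base64.b64decode(binary.text)
        if _ACC_ZLIB in accessions:
            raw = zlib.decompress(raw)
        elif _ACC_NO_COMPRESSION not in accessions:
            raise FormatError(f"{path} scan {scan_id}: unsupported compression")
        if _ACC_FLOAT64 in accessions:
            fmt, size = "d", 8
        elif _ACC_FLOAT32 in accessions:
            fmt, size = "f", 4
        else:
            raise FormatError(f"{path} scan {scan_id}: unsupported binary precision")
        n = len(raw) // size
        values = np.asarray(struct.unpack(f"<{n}{fmt}", raw[: n * size]), dtype=float)
        if _ACC_MZ_ARRAY in accessions:
            mz = values
        elif _ACC_INTENSITY_ARRAY in accessions:
            intensity = values
    if mz is None or intensity is None:
        raise FormatError(f"{path} scan {scan_id}: missing m/z or intensity array")
    if len(mz) != len(intensity):
        raise FormatError(
            f"{path} scan {scan_id}: m/z and intensity lengths differ "
            f"({len(mz)} vs {len(intensity)})"
        )
    return mz, intensity
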