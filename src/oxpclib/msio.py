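"""Reading and writing centroided spectra (mzML and MGF).

MGF goes through pyteomics.  mzML is handled by a compact reader/writer
pair speaking the minimal PSI-MS vocabulary (ms level, polarity,
centroid flag, scan start time, selected precursor, base64 binary
arrays, 32/64-bit floats, optional zlib compression on read), enough to
round-trip this package's runs and to ingest standard centroided files.
"""

from __future__ import annotations

import base64
import struct
import zlib
from pathlib import Path
from typing import List, Sequence
from xml.etree import ElementTree
from xml.sax.saxutils import escape

import numpy as np
from pyteomics import mgf as _mgf

from .peakproc import Spectrum

__all__ = ["read_mzml", "write_mzml", "read_mgf", "write_mgf"]


def _encode(arr: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{arr.size}d", *arr.astype(float))).decode()


_CV = {
    "ms_level": "MS:1000511",
    "pos": "MS:1000130",
    "neg": "MS:1000129",
    "centroid": "MS:1000127",
    "scan_time": "MS:1000016",
    "selected_mz": "MS:1000744",
    "mz_array": "MS:1000514",
    "intensity_array": "MS:1000515",
    "float64": "MS:1000523",
    "no_compression": "MS:1000576",
}


def _spectrum_xml(idx: int, spec: Spectrum) -> str:
    pol = (
        f'<cvParam cvRef="MS" accession="{_CV["pos"]}" name="positive scan"/>'
        if spec.polarity == "+"
        else f'<cvParam cvRef="MS" accession="{_CV["neg"]}" name="negative scan"/>'
    )
    precursor = ""
    if spec.ms_level == 2:
        precursor = (
            "<precursorList count=\"1\"><precursor><selectedIonList count=\"1\">"
            "<selectedIon>"
            f'<cvParam cvRef="MS" accession="{_CV["selected_mz"]}" name="selected ion m/z" '
            f'value="{spec.precursor_mz:.6f}"/>'
            "</selectedIon></selectedIonList></precursor></precursorList>"
        )
    arrays = []
    for acc, name, arr in (
        (_CV["mz_array"], "m/z array", spec.mz),
        (_CV["intensity_array"], "intensity array", spec.intensity),
    ):
        b64 = _encode(arr)
        arrays.append(
            f'<binaryDataArray encodedLength="{len(b64)}">'
            f'<cvParam cvRef="MS" accession="{_CV["float64"]}" name="64-bit float"/>'
            f'<cvParam cvRef="MS" accession="{_CV["no_compression"]}" name="no compression"/>'
            f'<cvParam cvRef="MS" accession="{acc}" name="{name}"/>'
            f"<binary>{b64}</binary></binaryDataArray>"
        )
    return (
        f'<spectrum index="{idx}" id="scan={idx + 1}" defaultArrayLength="{spec.mz.size}">'
        f'<cvParam cvRef="MS" accession="{_CV["ms_level"]}" name="ms level" value="{spec.ms_level}"/>'
        f'<cvParam cvRef="MS" accession="{_CV["centroid"]}" name="centroid spectrum"/>'
        f"{pol}{precursor}"
        '<scanList count="1"><scan>'
        f'<cvParam cvRef="MS" accession="{_CV["scan_time"]}" name="scan start time" '
        f'value="{spec.scan_time:.6f}" unitName="minute" unitAccession="UO:0000031"/>'
        "</scan></scanList>"
        f'<binaryDataArrayList count="2">{"".join(arrays)}</binaryDataArrayList>'
        "</spectrum>"
    )


def write_mzml(spectra: Sequence[Spectrum], path: str | Path, run_id: str = "run") -> None:
    body = "".join(_spectrum_xml(i, s) for i, s in enumerate(spectra))
    xml = (
        '<?xml version="1.0" encoding="utf-8"?>'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">'
        '<cvList count="1"><cv id="MS" fullName="PSI-MS" '
        'URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/></cvList>'
        f'<run id="{escape(run_id)}">'
        f'<spectrumList count="{len(spectra)}" defaultDataProcessingRef="dp">{body}</spectrumList>'
        "</run></mzML>"
    )
    Path(path).write_text(xml)


def _decode_binary_array(node: "ElementTree.Element") -> np.ndarray:
    params = {p.get("accession"): p for p in node.iter() if p.tag.endswith("cvParam")}
    raw = ""
    for child in node:
        if child.tag.endswith("binary"):
            raw = child.text or ""
    data = base64.b64decode(raw)
    if "MS:1000574" in params:  # zlib compression
        data = zlib.decompress(data)
    fmt = "f" if "MS:1000521" in params else "d"  # 32- vs 64-bit float
    n = len(data) // struct.calcsize(fmt)
    return np.asarray(struct.unpack(f"<{n}{fmt}", data), dtype=float)


def read_mzml(path: str | Path) -> List[Spectrum]:
    out: List[Spectrum] = []
    for _, node in ElementTree.iterparse(str(path)):
        if not node.tag.endswith("}spectrum") and node.tag != "spectrum":
            continue
        if node.tag.endswith("}chromatogram"):
            continue
        params = {}
        for p in node.iter():
            if p.tag.endswith("cvParam"):
                params.setdefault(p.get("accession"), p)
        level = int(params["MS:1000511"].get("value")) if "MS:1000511" in params else 1
        polarity = "-" if "MS:1000129" in params else "+"
        t = 0.0
        if "MS:1000016" in params:
            p = params["MS:1000016"]
            t = float(p.get("value"))
            if p.get("unitName") == "second":
                t /= 60.0
        prec = None
        if "MS:1000744" in params:
            prec = float(params["MS:1000744"].get("value"))
        mz = intensity = np.empty(0)
        for arr_node in node.iter():
            if not arr_node.tag.endswith("binaryDataArray"):
                continue
            accs = {p.get("accession") for p in arr_node.iter() if p.tag.endswith("cvParam")}
            if "MS:1000514" in accs:
                mz = _decode_binary_array(arr_node)
            elif "MS:1000515" in accs:
                intensity = _decode_binary_array(arr_node)
        out.append(
            Spectrum(scan_time=t, polarity=polarity, ms_level=level,
                     precursor_mz=prec, mz=mz, intensity=intensity)
        )
        node.clear()
    return out


def write_mgf(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write MS2 spectra as MGF (MS1 scans are skipped; MGF is MS2-only)."""
    recs = []
    for i, s in enumerate(spectra):
        if s.ms_level != 2:
            continue
        recs.append(
            {
                "m/z array": s.mz,
                "intensity array": s.intensity,
                "params": {
                    "title": f"scan={i + 1}",
                    "pepmass": (s.precursor_mz, None),
                    "rtinseconds": s.scan_time * 60.0,
                    "charge": "1-" if s.polarity == "-" else "1+",
                },
            }
        )
    _mgf.write(recs, output=str(path), file_mode="w")


def read_mgf(path: str | Path) -> List[Spectrum]:
    out: List[Spectrum] = []
    with _mgf.MGF(str(path)) as reader:
        for rec in reader:
            params = rec["params"]
            charge = params.get("charge")
            polarity = "-" if charge and str(charge[0]).endswith("-") else "+"
            rt = float(params.get("rtinseconds", 0.0)) / 60.0
            out.append(
                Spectrum(
                    scan_time=rt,
                    polarity=polarity,
                    ms_level=2,
                    precursor_mz=float(params["pepmass"][0]),
                    mz=np.asarray(rec["m/z array"], dtype=float),
                    intensity=np.asarray(rec["intensity array"], dtype=float),
                )
            )
    return out
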