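"""Reading and writing the pipeline's on-disk formats.

Peak lists travel as plain CSV (``scan_rt_min``, ``mz``, ``intensity``) or
centroided mzML (read through pyteomics); manifests, feature tables and
reports are CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ION_COLUMNS, RawRun, check_manifest


def read_peaklist_csv(path, run_id: str | None = None, run_type: str = "study") -> RawRun:
    path = Path(path)
    ions = pd.read_csv(path)
    missing = [c for c in ION_COLUMNS if c not in ions.columns]
    if missing:
        raise ValueError(f"{path}: peak-list CSV lacks columns {missing}")
    ions = ions[ION_COLUMNS].sort_values(["scan_rt_min", "mz"], kind="mergesort",
                                         ignore_index=True)
    return RawRun(run_id=run_id or path.stem, run_type=run_type, ions=ions)


def write_peaklist_csv(run: RawRun, path) -> None:
    run.ions.to_csv(path, index=False)


def _decode_binary(elem, ns) -> np.ndarray:
    """Decode one mzML binaryDataArray (64/32-bit float, zlib or none)."""
    import base64
    import zlib

    accessions = {cv.get("accession") for cv in elem.findall(f"{ns}cvParam")}
    text = elem.findtext(f"{ns}binary") or ""
    raw = base64.b64decode(text)
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path, run_id: str | None = None, run_type: str = "study") -> RawRun:
    """Read a centroided mzML file into a RawRun (MS1 scans only).

    A compact reader for the standard subset (plain or zlib-compressed
    32/64-bit float arrays); retention times are converted to minutes
    regardless of the file's declared unit.
    """
    import xml.etree.ElementTree as ET

    path = Path(path)
    root = ET.parse(path).getroot()
    ns = root.tag.split("}")[0] + "}" if root.tag.startswith("{") else ""
    rts, mzs, ints = [], [], []
    for spec in root.iter(f"{ns}spectrum"):
        params = {cv.get("accession"): cv for cv in spec.findall(f"{ns}cvParam")}
        level = params.get("MS:1000511")
        if level is not None and level.get("value") not in ("1", "", None):
            continue
        scan = spec.find(f"{ns}scanList/{ns}scan")
        minutes = 0.0
        if scan is not None:
            for cv in scan.findall(f"{ns}cvParam"):
                if cv.get("accession") == "MS:1000016":
                    minutes = float(cv.get("value"))
                    if (cv.get("unitName") or "minute").startswith("second"):
                        minutes /= 60.0
        mz = inten = None
        for arr in spec.findall(f"{ns}binaryDataArrayList/{ns}binaryDataArray"):
            acc = {cv.get("accession") for cv in arr.findall(f"{ns}cvParam")}
            if "MS:1000514" in acc:
                mz = _decode_binary(arr, ns)
            elif "MS:1000515" in acc:
                inten = _decode_binary(arr, ns)
        if mz is None or inten is None or len(mz) == 0:
            continue
        keep = inten > 0
        rts.append(np.full(int(keep.sum()), minutes))
        mzs.append(mz[keep])
        ints.append(inten[keep])
    if not rts:
        raise ValueError(f"{path}: no MS1 spectra found")
    ions = pd.DataFrame({
        "scan_rt_min": np.concatenate(rts),
        "mz": np.concatenate(mzs),
        "intensity": np.concatenate(ints),
    }).sort_values(["scan_rt_min", "mz"], kind="mergesort", ignore_index=True)
    return RawRun(run_id=run_id or path.stem, run_type=run_type, ions=ions)


def read_run(path, run_id=None, run_type: str = "study") -> RawRun:
    path = Path(path)
    if path.suffix.lower() == ".mzml":
        return read_mzml(path, run_id=run_id, run_type=run_type)
    return read_peaklist_csv(path, run_id=run_id, run_type=run_type)


def read_manifest(path) -> pd.DataFrame:
    manifest = pd.read_csv(path, keep_default_na=False)
    return check_manifest(manifest)


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, index=False)
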