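"""Minimal mzML reading and writing for simulated MS1/MS2/MS3 spectra.

Writes a small, valid subset of mzML 1.1.0 — uncompressed 64-bit float
arrays, ms level, precursor linkage via ``spectrumRef`` and per-peak
noise estimates as a named non-standard data array — and reads the same
subset back.  No installed Python library in this stack both writes and
reads mzML, so the subset is implemented here; files it produces open
in standard readers (validated against Bioconductor's mzR in the test
suite).  Ground-truth annotations do not belong in mzML and travel in a
sidecar TSV instead.
"""
from __future__ import annotations

import base64
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import TMT10_CHANNEL_NAMES
from .spectra import Precursor, SpectrumRecord

_NS = "http://psi.hupo.org/ms/mzml"

_CV = {
    "ms_level": ("MS:1000511", "ms level"),
    "ms1": ("MS:1000579", "MS1 spectrum"),
    "msn": ("MS:1000580", "MSn spectrum"),
    "float64": ("MS:1000523", "64-bit float"),
    "nocomp": ("MS:1000576", "no compression"),
    "mz_array": ("MS:1000514", "m/z array"),
    "int_array": ("MS:1000515", "intensity array"),
    "nonstd": ("MS:1000786", "non-standard data array"),
    "iso_target": ("MS:1000827", "isolation window target m/z"),
    "iso_lower": ("MS:1000828", "isolation window lower offset"),
    "iso_upper": ("MS:1000829", "isolation window upper offset"),
    "sel_mz": ("MS:1000744", "selected ion m/z"),
    "charge": ("MS:1000041", "charge state"),
}

NOISE_ARRAY_NAME = "noise array"


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode()


def _cv(key: str, value: str = "") -> str:
    acc, name = _CV[key]
    return f'<cvParam cvRef="MS" accession="{acc}" name="{name}" value="{value}"/>'


def _bda(key: str, arr: np.ndarray, nonstd_name: str | None = None) -> str:
    data = _b64(arr)
    name_param = _cv("nonstd", nonstd_name) if nonstd_name else _cv(key)
    return (
        f'<binaryDataArray encodedLength="{len(data)}">'
        + _cv("float64") + _cv("nocomp") + name_param
        + f"<binary>{data}</binary></binaryDataArray>"
    )


def write_mzml(spectra: list[SpectrumRecord], path) -> None:
    """Serialize a spectrum stream to mzML (deterministic byte output)."""
    parts = [
        '<?xml version="1.0" encoding="utf-8"?>\n'
        f'<mzML xmlns="{_NS}" version="1.1.0">\n'
        '<cvList count="1"><cv id="MS" fullName="PSI-MS" '
        'URI="http://purl.obolibrary.org/obo/ms.obo"/></cvList>\n'
        f'<run id="simulated"><spectrumList count="{len(spectra)}">\n'
    ]
    for idx, s in enumerate(spectra):
        parts.append(
            f'<spectrum index="{idx}" id="scan={s.scan_id}" defaultArrayLength="{s.n_peaks}">'
        )
        parts.append(_cv("ms_level", str(s.ms_level)))
        parts.append(_cv("ms1") if s.ms_level == 1 else _cv("msn"))
        if s.precursor is not None:
            p = s.precursor
            parts.append(
                f'<precursorList count="1"><precursor spectrumRef="scan={p.parent_scan_id}">'
                "<isolationWindow>"
                + _cv("iso_target", repr(p.mz))
                + _cv("iso_lower", repr(p.isolation_half_width))
                + _cv("iso_upper", repr(p.isolation_half_width))
                + "</isolationWindow>"
                '<selectedIonList count="1"><selectedIon>'
                + _cv("sel_mz", repr(p.mz))
                + _cv("charge", str(p.charge))
                + "</selectedIon></selectedIonList><activation/></precursor></precursorList>"
            )
        parts.append('<binaryDataArrayList count="3">')
        parts.append(_bda("mz_array", s.mz))
        parts.append(_bda("int_array", s.intensity))
        parts.append(_bda("nonstd", s.noise, nonstd_name=NOISE_ARRAY_NAME))
        parts.append("</binaryDataArrayList></spectrum>\n")
    parts.append("</spectrumList></run></mzML>\n")
    Path(path).write_text("".join(parts))


def _decode(elem) -> np.ndarray:
    binary = elem.find(f"{{{_NS}}}binary")
    raw = base64.b64decode(binary.text or "")
    return np.frombuffer(raw, dtype="<f8").copy()


def read_mzml(path) -> list[SpectrumRecord]:
    """Parse the mzML subset written by :func:`write_mzml`."""
    tree = ET.parse(path)
    out: list[SpectrumRecord] = []
    for spec in tree.iter(f"{{{_NS}}}spectrum"):
        scan_id = int(spec.get("id").split("=")[-1])
        params = {
            p.get("accession"): p.get("value")
            for p in spec.findall(f"{{{_NS}}}cvParam")
        }
        ms_level = int(params["MS:1000511"])
        arrays: dict[str, np.ndarray] = {}
        for bda in spec.iter(f"{{{_NS}}}binaryDataArray"):
            name = None
            for p in bda.findall(f"{{{_NS}}}cvParam"):
                acc = p.get("accession")
                if acc == "MS:1000514":
                    name = "mz"
                elif acc == "MS:1000515":
                    name = "intensity"
                elif acc == "MS:1000786":
                    name = p.get("value")
            if name:
                arrays[name] = _decode(bda)
        precursor = None
        prec_elem = spec.find(f"{{{_NS}}}precursorList/{{{_NS}}}precursor")
        if prec_elem is not None:
            parent = int(prec_elem.get("spectrumRef").split("=")[-1])
            pparams = {
                p.get("accession"): p.get("value") for p in prec_elem.iter(f"{{{_NS}}}cvParam")
            }
            precursor = Precursor(
                mz=float(pparams["MS:1000744"]),
                charge=int(pparams.get("MS:1000041", 0)),
                isolation_half_width=float(pparams.get("MS:1000828", 0.25)),
                parent_scan_id=parent,
            )
        noise = arrays.get(NOISE_ARRAY_NAME)
        if noise is None:
            noise = np.ones(len(arrays["mz"]))
        out.append(
            SpectrumRecord(
                scan_id=scan_id,
                ms_level=ms_level,
                mz=arrays["mz"],
                intensity=arrays["intensity"],
                noise=noise,
                precursor=precursor,
            )
        )
    return out


def write_ground_truth_sidecar(spectra: list[SpectrumRecord], path) -> None:
    """TSV of per-MS3-scan ground truth: peptide, interference, true intensities."""
    rows = []
    for s in spectra:
        if s.ms_level != 3 or not s.annotations:
            continue
        row = {
            "scan_id": s.scan_id,
            "peptide": s.annotations.get("peptide", ""),
            "proteins": ";".join(s.annotations.get("proteins", ())),
            "interference": s.annotations.get("interference", np.nan),
            "plex_id": s.annotations.get("plex_id", ""),
        }
        true_int = s.annotations.get("true_intensity")
        if true_int is not None:
            for name, v in zip(TMT10_CHANNEL_NAMES, true_int):
                row[f"true_{name}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ground_truth_sidecar(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def attach_annotations(spectra: list[SpectrumRecord], sidecar: pd.DataFrame) -> None:
    """Re-attach sidecar ground truth to MS3 records (in place)."""
    true_cols = [c for c in sidecar.columns if c.startswith("true_")]
    by_scan = sidecar.set_index("scan_id")
    for s in spectra:
        if s.ms_level != 3 or s.scan_id not in by_scan.index:
            continue
        row = by_scan.loc[s.scan_id]
        s.annotations = {
            "peptide": row["peptide"],
            "proteins": tuple(str(row["proteins"]).split(";")) if row["proteins"] else (),
            "interference": float(row["interference"]),
            "plex_id": row.get("plex_id", ""),
            "true_intensity": row[true_cols].to_numpy(dtype=float) if true_cols else None,
        }
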