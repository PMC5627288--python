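"""Reporter-ion extraction, impurity correction and quantifiability filters.

Reporter signal is read from MS3 scans inside a 0.003 Th window centred
on each channel's theoretical m/z, taking the peak closest to the
theoretical value.  Observed S/N vectors are deconvolved through the
isotope-impurity matrix by nonnegative least squares, precursor
isolation specificity is computed from the MS1 survey scan, and
peptides are kept only if total S/N exceeds 200 and specificity
exceeds 0.75 (both strict).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .channels import ChannelDefinition, ImpurityMatrix, default_channels
from .masses import C13_C12_DELTA
from .spectra import SpectrumRecord

DEFAULT_MIN_TOTAL_SN = 200.0
DEFAULT_MIN_SPECIFICITY = 0.75
CONDITION_LIMIT = 1e8


@dataclass
class QuantifiedPeptide:
    """A quantifiable PSM: impurity-corrected 10-vector of reporter S/N."""

    scan_id: int
    peptide: str
    protein: str
    raw_sn: np.ndarray
    corrected_sn: np.ndarray
    isolation_specificity: float

    @property
    def total_sn(self) -> float:
        """Summed corrected S/N over all ten channels (empty windows count 0)."""
        return float(self.corrected_sn.sum())


def extract_reporters(
    ms3: SpectrumRecord,
    channels: tuple[ChannelDefinition, ...] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-channel (intensity, noise, S/N) from an MS3 scan.

    For each channel the peak inside the extraction window whose m/z is
    closest to the theoretical value is recorded; a channel with no
    in-window peak contributes zero signal (S/N 0) rather than missing.
    """
    channels = channels if channels is not None else default_channels()
    if ms3.ms_level != 3:
        raise ValueError(f"scan {ms3.scan_id} is MS{ms3.ms_level}, not MS3")
    if np.any(np.diff(ms3.mz) < 0):
        raise ValueError(f"scan {ms3.scan_id}: peak list not sorted by m/z")
    n = len(channels)
    intensity = np.zeros(n)
    noise = np.ones(n)
    sn = np.zeros(n)
    for i, ch in enumerate(channels):
        d = np.abs(ms3.mz - ch.mz)
        in_win = d <= ch.half_width
        if not in_win.any():
            continue
        j = np.flatnonzero(in_win)[np.argmin(d[in_win])]
        intensity[i] = ms3.intensity[j]
        noise[i] = ms3.noise[j]
        sn[i] = ms3.intensity[j] / ms3.noise[j]
    return intensity, noise, sn


def correct_isotope_impurities(raw: np.ndarray, impurity: ImpurityMatrix) -> np.ndarray:
    """Solve observed = M @ true for the true channel vector.

    Nonnegative least squares guarantees a nonnegative result even when
    noise makes the plain inverse go negative; the identity matrix is a
    strict pass-through.
    """
    raw = np.asarray(raw, dtype=float)
    M = impurity.matrix
    if raw.shape != (M.shape[0],):
        raise ValueError(f"expected a length-{M.shape[0]} vector, got shape {raw.shape}")
    if impurity.is_identity:
        return raw.copy()
    cond = np.linalg.cond(M)
    if cond > CONDITION_LIMIT:
        raise ValueError(f"impurity matrix is ill-conditioned (cond={cond:.3g}); cannot deconvolve")
    corrected, _ = nnls(M, raw)
    return corrected


def compute_isolation_specificity(
    ms2_precursor,
    ms1: SpectrumRecord,
    envelope_ppm: float = 10.0,
    max_isotope: int = 3,
) -> float:
    """Fraction of isolation-window ion current owned by the precursor.

    Peaks within ``envelope_ppm`` of the precursor m/z plus k·(1.00335/z)
    for k = 0..``max_isotope`` count as the precursor's isotopic
    envelope; specificity is envelope intensity over total intensity
    inside the window.  An empty window returns 0 with a warning.
    """
    if ms1 is None:
        raise ValueError(f"parent survey scan {ms2_precursor.parent_scan_id} not found")
    if ms1.scan_id != ms2_precursor.parent_scan_id:
        raise ValueError(
            f"survey scan mismatch: precursor points to scan {ms2_precursor.parent_scan_id}, "
            f"got scan {ms1.scan_id}"
        )
    lo = ms2_precursor.mz - ms2_precursor.isolation_half_width
    hi = ms2_precursor.mz + ms2_precursor.isolation_half_width
    in_win = (ms1.mz >= lo) & (ms1.mz <= hi)
    total = ms1.intensity[in_win].sum()
    if total <= 0:
        warnings.warn(f"empty isolation window for scan {ms2_precursor.parent_scan_id}; specificity 0")
        return 0.0
    env_mz = ms2_precursor.mz + np.arange(max_isotope + 1) * C13_C12_DELTA / ms2_precursor.charge
    is_env = np.zeros(len(ms1.mz), dtype=bool)
    for m in env_mz:
        is_env |= np.abs(ms1.mz - m) <= m * envelope_ppm * 1e-6
    env = ms1.intensity[in_win & is_env].sum()
    return float(env / total)


def filter_quantifiable(
    quants: list[QuantifiedPeptide],
    min_total_sn: float = DEFAULT_MIN_TOTAL_SN,
    min_specificity: float = DEFAULT_MIN_SPECIFICITY,
) -> list[QuantifiedPeptide]:
    """Keep peptides with total S/N > ``min_total_sn`` and specificity
    > ``min_specificity`` — both inequalities strict, so values exactly
    at a threshold are rejected."""
    kept = [
        q for q in quants
        if q.total_sn > min_total_sn and q.isolation_specificity > min_specificity
    ]
    return kept


def quantify_spectra(
    spectra: list[SpectrumRecord],
    peptide_by_scan: dict[int, tuple[str, str]],
    impurity: ImpurityMatrix | None = None,
    channels: tuple[ChannelDefinition, ...] | None = None,
) -> list[QuantifiedPeptide]:
    """Quantify every MS3 scan whose parent MS2 has an accepted PSM.

    ``peptide_by_scan`` maps MS2 scan id -> (peptide, protein group
    representative), normally built from the identification output.
    Isolation specificity is computed from the MS1 grandparent of each
    MS3 scan.
    """
    channels = channels if channels is not None else default_channels()
    impurity = impurity if impurity is not None else ImpurityMatrix.default()
    by_id = {s.scan_id: s for s in spectra}
    out: list[QuantifiedPeptide] = []
    for spec in spectra:
        if spec.ms_level != 3:
            continue
        ms2 = by_id.get(spec.precursor.parent_scan_id)
        if ms2 is None or ms2.scan_id not in peptide_by_scan:
            continue
        peptide, protein = peptide_by_scan[ms2.scan_id]
        ms1 = by_id.get(ms2.precursor.parent_scan_id)
        specificity = compute_isolation_specificity(ms2.precursor, ms1)
        _, _, raw_sn = extract_reporters(spec, channels)
        corrected = correct_isotope_impurities(raw_sn, impurity)
        out.append(
            QuantifiedPeptide(
                scan_id=spec.scan_id,
                peptide=peptide,
                protein=protein,
                raw_sn=raw_sn,
                corrected_sn=corrected,
                isolation_specificity=specificity,
            )
        )
    return out


def quantified_to_frame(quants: list[QuantifiedPeptide], channel_names: tuple[str, ...]) -> pd.DataFrame:
    """Quantified peptides as a table with one corrected-S/N column per channel."""
    rows = {
        "scan_id": [q.scan_id for q in quants],
        "peptide": [q.peptide for q in quants],
        "protein": [q.protein for q in quants],
        "isolation_specificity": [q.isolation_specificity for q in quants],
        "total_sn": [q.total_sn for q in quants],
    }
    mat = np.array([q.corrected_sn for q in quants]).reshape(len(quants), len(channel_names))
    for i, name in enumerate(channel_names):
        rows[f"sn_{name}"] = mat[:, i]
    return pd.DataFrame(rows)
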