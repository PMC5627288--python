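"""In-memory spectrum container shared by the simulator, search and quant stages."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Precursor:
    """Precursor metadata attached to MS2/MS3 scans."""

    mz: float
    charge: int
    isolation_half_width: float
    parent_scan_id: int


@dataclass
class SpectrumRecord:
    """One MS1/MS2/MS3 scan: a peak list with per-peak noise estimates.

    ``noise`` is the instrument noise-band estimate at each peak's m/z,
    so S/N = intensity / noise is defined for every peak.  MS2 and MS3
    records must carry precursor metadata linking them to their parent
    scan; simulated scans additionally carry ground-truth annotations
    (generating peptide, true channel intensities, interference
    fraction) used only for testing and QC.
    """

    scan_id: int
    ms_level: int
    mz: np.ndarray
    intensity: np.ndarray
    noise: np.ndarray
    precursor: Precursor | None = None
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.noise = np.asarray(self.noise, dtype=float)
        if not (len(self.mz) == len(self.intensity) == len(self.noise)):
            raise ValueError("mz, intensity and noise arrays must have equal length")
        if self.ms_level not in (1, 2, 3):
            raise ValueError(f"ms_level must be 1, 2 or 3, got {self.ms_level}")
        if np.any(np.diff(self.mz) < 0):
            raise ValueError(f"scan {self.scan_id}: peak list must be sorted by m/z")
        if np.any(self.noise <= 0):
            raise ValueError(f"scan {self.scan_id}: noise estimates must be positive")
        if self.ms_level > 1 and self.precursor is None:
            raise ValueError(f"scan {self.scan_id}: MS{self.ms_level} scan requires precursor metadata")

    @property
    def n_peaks(self) -> int:
        return len(self.mz)
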