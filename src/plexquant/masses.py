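"""Monoisotopic mass bookkeeping for TMT-labelled tryptic peptides.

All peptides carry the fixed modifications used throughout the pipeline:
carbamidomethyl on Cys and a TMT 10-plex tag on the N-terminus and on
every Lys side chain.  Variable modifications are carried as metadata
only and do not enter mass computation.
"""
from __future__ import annotations

import numpy as np
from pyteomics import mass as _pmass

PROTON_MASS = 1.00727646688
WATER_MASS = 18.0105646863
C13_C12_DELTA = 1.0033548378
ELECTRON_MASS = 0.00054857990907

#: monoisotopic mass added by one TMT 10-plex label (N-terminus or Lys).
TMT10_TAG_MASS = 229.162932
#: fixed carbamidomethylation of cysteine.
CARBAMIDOMETHYL_MASS = 57.021464

# residue masses from pyteomics, with the two static modifications folded in
_AA_MASS = dict(_pmass.std_aa_mass)
_AA_MASS["C"] = _AA_MASS["C"] + CARBAMIDOMETHYL_MASS
_AA_MASS["K"] = _AA_MASS["K"] + TMT10_TAG_MASS

VALID_RESIDUES = frozenset(_pmass.std_aa_mass) - {"O", "U"}


def residue_masses(sequence: str) -> np.ndarray:
    """Per-residue monoisotopic masses (static mods included)."""
    try:
        return np.array([_AA_MASS[a] for a in sequence])
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"unknown residue {exc} in {sequence!r}") from None


def peptide_mass(sequence: str) -> float:
    """Neutral monoisotopic mass of a labelled peptide (Da).

    Includes water, the N-terminal TMT tag and one tag per Lys.
    """
    return float(residue_masses(sequence).sum() + WATER_MASS + TMT10_TAG_MASS)


def precursor_mz(sequence: str, charge: int) -> float:
    """m/z of the [M + z·H]^z+ precursor."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (peptide_mass(sequence) + charge * PROTON_MASS) / charge


def fragment_mzs(sequence: str) -> np.ndarray:
    """Singly charged b- and y-ion m/z values, sorted ascending.

    The fragmentation model used by both the simulator and the search
    scorer: b ions keep the N-terminal tag, y ions keep the C-terminal
    water; Lys tags travel with their residue.  Only unit-charge ions
    are generated.
    """
    res = residue_masses(sequence)
    if len(res) < 2:
        return np.empty(0)
    prefix = np.cumsum(res[:-1])
    b = prefix + TMT10_TAG_MASS + PROTON_MASS
    suffix = np.cumsum(res[::-1][:-1])
    y = suffix + WATER_MASS + PROTON_MASS
    return np.sort(np.concatenate([b, y]))
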