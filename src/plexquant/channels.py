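"""TMT 10-plex reporter channel definitions and the isotope-impurity model.

The ten reporter ions are immonium-like cations of composition C8H16N+
with increasing numbers of 13C / 15N substitutions; their monoisotopic
m/z values are fixed constants of the reagent chemistry.  Imperfect
isotopic enrichment makes a small fraction of each channel's reporter
signal appear in neighbouring channels; that cross-talk is described by
a column-stochastic-ish leakage matrix which quantification inverts.
"""
from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

TMT10_CHANNEL_NAMES: tuple[str, ...] = (
    "126", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C", "131",
)

#: theoretical reporter-ion m/z (Th), derivable from the isotopologue
#: composition C8H16N+ with 0-4 13C and 0-1 15N substitutions.
TMT10_REPORTER_MZ: dict[str, float] = {
    "126": 126.127726,
    "127N": 127.124761,
    "127C": 127.131081,
    "128N": 128.128116,
    "128C": 128.134436,
    "129N": 129.131471,
    "129C": 129.137790,
    "130N": 130.134825,
    "130C": 130.141145,
    "131": 131.138180,
}

DEFAULT_WINDOW_HALF_WIDTH = 0.0015  # Th; a 0.003 Th full extraction window


@dataclass(frozen=True)
class ChannelDefinition:
    """One reporter channel: name, theoretical m/z and extraction window."""

    name: str
    mz: float
    half_width: float = DEFAULT_WINDOW_HALF_WIDTH


def default_channels(half_width: float = DEFAULT_WINDOW_HALF_WIDTH) -> tuple[ChannelDefinition, ...]:
    """The ten TMT10 channels with non-overlapping extraction windows."""
    chans = tuple(
        ChannelDefinition(name, TMT10_REPORTER_MZ[name], half_width)
        for name in TMT10_CHANNEL_NAMES
    )
    mzs = np.array([c.mz for c in chans])
    if not np.all(np.diff(mzs) > 0):
        raise ValueError("channel m/z values must be strictly increasing")
    if np.any(np.diff(mzs) <= 2 * half_width):
        raise ValueError("extraction windows overlap; reduce half_width")
    return chans


class ImpurityMatrix:
    """Reporter-ion leakage matrix M.

    ``M[i, j]`` is the fraction of channel ``j``'s true signal that is
    detected in channel ``i``.  Columns may sum to less than 1 when
    leakage falls outside the plex.
    """

    def __init__(self, matrix: np.ndarray, channels: tuple[str, ...] = TMT10_CHANNEL_NAMES):
        M = np.asarray(matrix, dtype=float)
        n = len(channels)
        if M.shape != (n, n):
            raise ValueError(f"impurity matrix must be {n}x{n}, got {M.shape}")
        if np.any(M < 0):
            raise ValueError("impurity matrix entries must be nonnegative")
        if np.any(M.sum(axis=0) > 1 + 1e-9):
            raise ValueError("impurity matrix column sums must not exceed 1")
        if np.any(np.diag(M) < 0.8):
            raise ValueError("impurity matrix diagonal below 0.8 is not a plausible reagent")
        self.matrix = M
        self.channels = tuple(channels)

    @property
    def is_identity(self) -> bool:
        return bool(np.array_equal(self.matrix, np.eye(len(self.channels))))

    @classmethod
    def identity(cls, channels: tuple[str, ...] = TMT10_CHANNEL_NAMES) -> "ImpurityMatrix":
        return cls(np.eye(len(channels)), channels)

    @classmethod
    def from_leakage_table(cls, table: pd.DataFrame) -> "ImpurityMatrix":
        """Build M from a manufacturer-style leakage table.

        Expected columns: ``channel, minus2, minus1, plus1, plus2`` with
        leakage given in percent of the channel's own signal.  The
        diagonal is 100 minus the listed leakage; leakage beyond the
        first or last channel is lost.
        """
        names = [str(c) for c in table["channel"]]
        n = len(names)
        M = np.zeros((n, n))
        offsets = {"minus2": -2, "minus1": -1, "plus1": 1, "plus2": 2}
        for j in range(n):
            row = table.iloc[j]
            total_leak = 0.0
            for col, off in offsets.items():
                frac = float(row[col]) / 100.0
                total_leak += frac
                i = j + off
                if 0 <= i < n:
                    M[i, j] = frac
            M[j, j] = 1.0 - total_leak
        return cls(M, tuple(names))

    @classmethod
    def default(cls) -> "ImpurityMatrix":
        """The packaged default leakage fixture (v1).

        The reagent certificate values are lot specific and not public;
        this fixture uses representative magnitudes (1-3% to adjacent
        channels, up to 0.3% two channels away).
        """
        text = resources.files("plexquant").joinpath("data/tmt10_impurity_v1.tsv").read_text()
        table = pd.read_csv(io.StringIO(text), sep="\t", comment="#")
        return cls.from_leakage_table(table)
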