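"""Channel normalization, protein roll-up and cross-plex aggregation.

Within each plex, channel loadings are equalized by scaling every
channel so all ten summed S/N values match (the target is the mean of
the channel sums; any common constant gives the same downstream
ratios).  Peptide rows are then summed per protein group, and the two
plexes of a tissue are merged into one protein x 20-sample table.  The
design has no bridge channel, so plexes are made comparable by internal
reference scaling: each protein's channel values are divided by its
within-plex row mean before concatenation (configurable).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import PlexDesign

PLEX_SCALINGS = ("row_mean", "row_median", "none")


@dataclass
class ProteinQuantTable:
    """Protein x sample abundance table for one tissue.

    ``data`` rows are protein accessions, columns sample ids; ``groups``
    maps each sample id to its group label.  Missing values (a protein
    seen in only one plex) stay missing — they are never zero-imputed.
    """

    tissue: str
    data: pd.DataFrame
    groups: pd.Series

    def __post_init__(self):
        missing = [c for c in self.data.columns if c not in self.groups.index]
        if missing:
            raise ValueError(f"samples without group labels: {missing}")
        self.groups = self.groups.loc[list(self.data.columns)]

    def group_columns(self, group: str) -> list[str]:
        return [c for c in self.data.columns if self.groups[c] == group]


def normalize_channels(peptide_matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Equalize channel sums within one plex.

    ``factor_j = mean(channel sums) / sum_j``; every value in channel j
    is multiplied by its factor, so all post-normalization channel sums
    equal the mean of the original sums.  A channel with zero total
    signal cannot be equalized and raises an error naming it.
    """
    if peptide_matrix.shape[0] < 1:
        raise ValueError("normalization requires at least one quantifiable peptide")
    sums = peptide_matrix.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"channel(s) with zero total signal cannot be normalized: {list(zero.index)}")
    factors = sums.mean() / sums
    return peptide_matrix * factors, factors


def rollup_proteins(normalized: pd.DataFrame, assignment: pd.Series) -> pd.DataFrame:
    """Sum normalized peptide rows per protein group.

    ``assignment`` maps each peptide row (by index) to its protein-group
    representative; every row must be assigned (the identification stage
    produces a partition).  Proteins with no surviving peptides are
    simply absent.  The grand total is conserved.
    """
    unassigned = normalized.index.difference(assignment.index)
    if len(unassigned):
        raise ValueError(f"peptide rows without protein assignment: {list(unassigned)[:5]}")
    prot = normalized.groupby(assignment.loc[normalized.index].to_numpy()).sum()
    prot.index.name = "accession"
    return prot.sort_index()


def aggregate_plexes(
    plex_tables: dict[str, pd.DataFrame],
    design: PlexDesign,
    tissue: str,
    scaling: str = "row_mean",
) -> ProteinQuantTable:
    """Merge the per-plex protein tables of one tissue into a single report.

    With ``row_mean`` scaling (default) each protein's channel values
    are divided by that protein's within-plex row mean before the
    columns are concatenated, removing per-plex loading and sampling-
    depth factors; ``row_median`` uses the row median, ``none`` merges
    raw values.  A protein present in only one plex keeps its 10 values
    plus 10 missing.  Column order follows the design.
    """
    if scaling not in PLEX_SCALINGS:
        raise ValueError(f"scaling must be one of {PLEX_SCALINGS}")
    plexes = design.plexes_for(tissue)
    if set(plex_tables) != {p.plex_id for p in plexes}:
        raise ValueError(
            f"expected tables for plexes {[p.plex_id for p in plexes]}, got {sorted(plex_tables)}"
        )
    all_samples: list[str] = []
    groups = {}
    for p in plexes:
        for c in p.channels:
            if c.subject in groups:
                raise ValueError(f"duplicate sample id across plexes: {c.subject}")
            groups[c.subject] = c.group
            all_samples.append(c.subject)

    scaled = []
    for p in plexes:
        tab = plex_tables[p.plex_id].copy()
        expected = [c.subject for c in p.channels]
        if list(tab.columns) != expected:
            tab = tab.loc[:, expected]
        if scaling == "row_mean":
            ref = tab.mean(axis=1)
        elif scaling == "row_median":
            ref = tab.median(axis=1)
        else:
            ref = None
        if ref is not None:
            tab = tab.div(ref.replace(0, np.nan), axis=0)
        scaled.append(tab)

    merged = pd.concat(scaled, axis=1, join="outer").loc[:, all_samples].sort_index()
    merged = merged.dropna(how="all")
    return ProteinQuantTable(tissue=tissue, data=merged, groups=pd.Series(groups))
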