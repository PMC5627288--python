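"""Tabular and FASTA I/O, including the supplementary-dataset reader.

All internal tables are TSV with documented headers.  The protein quant
table carries a small ``#``-prefixed header block (tissue and sample ->
group mapping) so the file is self-describing — the same shape a reader
expects for a published per-tissue protein quantification supplement.
"""
from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import fasta as _fasta

from .design import GROUPS, GROUP_CONTROL, GROUP_GLAUCOMA
from .rollup import ProteinQuantTable

logger = logging.getLogger(__name__)


def write_fasta(proteins: list[tuple[str, str]], path) -> None:
    _fasta.write(proteins, str(path), file_mode="w")


def read_fasta(path) -> list[tuple[str, str]]:
    out = []
    with _fasta.read(str(path)) as reader:
        for description, sequence in reader:
            out.append((description.split()[0], sequence))
    return out


def write_quant_table(table: ProteinQuantTable, path) -> None:
    path = Path(path)
    lines = [f"# tissue\t{table.tissue}"]
    lines.append("# groups\t" + ";".join(f"{s}={g}" for s, g in table.groups.items()))
    body = table.data.to_csv(sep="\t", index_label="accession", float_format="%.10g")
    path.write_text("\n".join(lines) + "\n" + body)


def read_quant_table(path) -> ProteinQuantTable:
    path = Path(path)
    tissue = ""
    groups: dict[str, str] = {}
    skip = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            key, _, value = line[1:].strip().partition("\t")
            if key == "tissue":
                tissue = value
            elif key == "groups":
                groups = dict(item.split("=") for item in value.split(";"))
    data = pd.read_csv(path, sep="\t", skiprows=skip, index_col="accession").astype(float)
    return ProteinQuantTable(tissue=tissue, data=data, groups=pd.Series(groups))


_ID_CANDIDATES = ("accession", "protein", "protein_id", "uniprot", "id")
_FC_PATTERNS = (r"fold", r"\bfc\b", r"ratio")
_P_PATTERNS = (r"p[-_ ]?value", r"\bpval", r"^p$")


def _find_column(columns, patterns) -> str | None:
    for col in columns:
        low = str(col).strip().lower()
        for pat in patterns:
            if re.search(pat, low):
                return col
    return None


def read_supplementary_table(
    path,
    id_column: str | None = None,
    tissue: str = "",
    group_map: dict[str, str] | None = None,
):
    """Parse a published protein-quantification supplement.

    Auto-detects the layout: either per-sample abundance columns (group
    labels inferred from headers containing ``control``/``glaucoma`` or
    supplied via ``group_map``) giving a :class:`ProteinQuantTable`, or
    precomputed fold-change/p-value columns giving a DataFrame ready for
    differential classification.  Duplicated accessions are an error.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    if id_column is None:
        id_column = next(
            (c for c in df.columns if str(c).strip().lower() in _ID_CANDIDATES), None
        )
        if id_column is None:
            obj_cols = [c for c in df.columns if df[c].dtype == object]
            id_column = obj_cols[0] if obj_cols else None
    if id_column is None or id_column not in df.columns:
        raise ValueError(
            f"no protein identifier column found; headers are {list(df.columns)}"
        )
    dupes = df[id_column][df[id_column].duplicated()].unique()
    if len(dupes):
        raise ValueError(f"duplicated accessions in {path.name}: {list(dupes)[:10]}")
    df = df.set_index(id_column)
    logger.info("read %d proteins from %s", len(df), path.name)

    if group_map is None:
        group_map = {}
        for col in df.columns:
            low = str(col).lower()
            if "control" in low or low.startswith(("ctrl", "c_")):
                group_map[col] = GROUP_CONTROL
            elif "glaucoma" in low or low.startswith(("glau", "g_")):
                group_map[col] = GROUP_GLAUCOMA
    sample_cols = [c for c in df.columns if c in group_map]
    if sample_cols:
        data = df[sample_cols].apply(pd.to_numeric, errors="coerce")
        return ProteinQuantTable(
            tissue=tissue, data=data, groups=pd.Series({c: group_map[c] for c in sample_cols})
        )

    fc_col = _find_column(df.columns, _FC_PATTERNS)
    p_col = _find_column(df.columns, _P_PATTERNS)
    if fc_col is None or p_col is None:
        raise ValueError(
            "table has neither recognizable sample columns nor fold-change/p-value "
            f"columns; headers are {list(df.columns)}"
        )
    fc = pd.to_numeric(df[fc_col], errors="coerce")
    out = pd.DataFrame(
        {
            "fold_change": fc,
            "log2_fc": np.log2(fc),
            "p_value": pd.to_numeric(df[p_col], errors="coerce"),
        },
        index=df.index,
    )
    return out


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
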