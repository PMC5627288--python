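"""Differential protein abundance and the associated QC surfaces.

A protein is called differential when it clears two gates at once: a
two-sided two-sample t-test on log2 abundances with p <= alpha (0.05),
and a fold change — mean(glaucoma)/mean(control) on the raw relative-
abundance scale — at or beyond the thresholds (>= 1.3 up, <= 0.77
down; 0.76 is selectable, both values appear in the source protocol).
No multiple-testing correction enters the calls; a Benjamini-Hochberg
q-value column is emitted for reference only.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average as _average_linkage, leaves_list
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .design import GROUP_CONTROL, GROUP_GLAUCOMA
from .rollup import ProteinQuantTable

DEFAULT_ALPHA = 0.05
DEFAULT_UP_FC = 1.3
DEFAULT_DOWN_FC = 0.77  # 0.76 selectable
DEFAULT_MIN_N = 3

CALL_UP = "up"
CALL_DOWN = "down"
CALL_UNCHANGED = "unchanged"
CALL_UNTESTABLE = "untestable"


def test_protein(
    control: np.ndarray,
    glaucoma: np.ndarray,
    min_n: int = DEFAULT_MIN_N,
    equal_var: bool = True,
    log_scale: bool = True,
) -> tuple[float, float]:
    """Fold change and two-sided t-test p-value for one protein.

    Fold change is mean(glaucoma)/mean(control) on the raw scale; the
    t-test runs on log2-transformed values by default (Student pooled
    variance; Welch via ``equal_var=False``).  Missing values are
    dropped; fewer than ``min_n`` per group makes the protein
    untestable (NaN, NaN).  Identical constant groups report p = 1.
    """
    c = np.asarray(control, dtype=float)
    g = np.asarray(glaucoma, dtype=float)
    c = c[~np.isnan(c)]
    g = g[~np.isnan(g)]
    if len(c) < min_n or len(g) < min_n:
        return float("nan"), float("nan")
    fc = g.mean() / c.mean()
    xc = np.log2(c) if log_scale else c
    xg = np.log2(g) if log_scale else g
    if xc.std() == 0 and xg.std() == 0:
        return fc, 1.0 if xc.mean() == xg.mean() else 0.0
    t, p = stats.ttest_ind(xg, xc, equal_var=equal_var)
    return float(fc), float(p)


def test_table(
    table: ProteinQuantTable,
    min_n: int = DEFAULT_MIN_N,
    equal_var: bool = True,
    log_scale: bool = True,
) -> pd.DataFrame:
    """Vectorized per-protein statistics over a quant table.

    Returns one row per protein: n_control, n_glaucoma, fold_change,
    log2_fc, p_value, q_value (Benjamini-Hochberg, reference only).
    """
    ctrl_cols = table.group_columns(GROUP_CONTROL)
    glau_cols = table.group_columns(GROUP_GLAUCOMA)
    C = table.data[ctrl_cols].to_numpy(dtype=float)
    G = table.data[glau_cols].to_numpy(dtype=float)
    n_c = (~np.isnan(C)).sum(axis=1)
    n_g = (~np.isnan(G)).sum(axis=1)
    mean_c = np.nanmean(np.where(np.isnan(C), np.nan, C), axis=1)
    mean_g = np.nanmean(np.where(np.isnan(G), np.nan, G), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_g / mean_c
        Xc = np.log2(C) if log_scale else C
        Xg = np.log2(G) if log_scale else G
    res = stats.ttest_ind(Xg, Xc, axis=1, equal_var=equal_var, nan_policy="omit")
    p = np.asarray(res.pvalue, dtype=float)
    # degenerate rows: zero variance in both groups
    var_c = np.nanvar(Xc, axis=1)
    var_g = np.nanvar(Xg, axis=1)
    degenerate = (var_c == 0) & (var_g == 0)
    p = np.where(degenerate, np.where(np.isclose(np.nanmean(Xc, axis=1), np.nanmean(Xg, axis=1)), 1.0, 0.0), p)
    untestable = (n_c < min_n) | (n_g < min_n)
    p = np.where(untestable, np.nan, p)
    fc = np.where(untestable, np.nan, fc)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = stats.false_discovery_control(p[ok], method="bh")
    return pd.DataFrame(
        {
            "n_control": n_c,
            "n_glaucoma": n_g,
            "fold_change": fc,
            "log2_fc": np.log2(fc),
            "p_value": p,
            "q_value": q,
        },
        index=table.data.index,
    )


def classify_differential(
    results: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    up_fc: float = DEFAULT_UP_FC,
    down_fc: float = DEFAULT_DOWN_FC,
) -> pd.DataFrame:
    """Dual-threshold calls: significance and fold change must both pass.

    Boundaries are inclusive (p <= alpha, fold change >= up_fc or
    <= down_fc).  Returns the input with a ``call`` column added.
    """
    if down_fc >= up_fc:
        raise ValueError(f"down threshold ({down_fc}) must be below up threshold ({up_fc})")
    if alpha <= 0 or up_fc <= 0 or down_fc <= 0:
        raise ValueError("thresholds must be positive")
    out = results.copy()
    p = out["p_value"].to_numpy(dtype=float)
    fc = out["fold_change"].to_numpy(dtype=float)
    call = np.full(len(out), CALL_UNCHANGED, dtype=object)
    call[np.isnan(p) | np.isnan(fc)] = CALL_UNTESTABLE
    sig = p <= alpha
    call[sig & (fc >= up_fc)] = CALL_UP
    call[sig & (fc <= down_fc)] = CALL_DOWN
    out["call"] = call
    return out


def summarize_calls(classified: pd.DataFrame) -> dict[str, int]:
    counts = classified["call"].value_counts()
    return {
        "up": int(counts.get(CALL_UP, 0)),
        "down": int(counts.get(CALL_DOWN, 0)),
        "unchanged": int(counts.get(CALL_UNCHANGED, 0)),
        "untestable": int(counts.get(CALL_UNTESTABLE, 0)),
    }


@dataclass
class VennOverlap:
    only_a: int
    shared: int
    only_b: int
    members_only_a: tuple[str, ...]
    members_shared: tuple[str, ...]
    members_only_b: tuple[str, ...]


def venn_overlap(set_a, set_b) -> VennOverlap:
    """Exact two-set overlap with membership lists (sorted)."""
    a, b = set(set_a), set(set_b)
    return VennOverlap(
        only_a=len(a - b),
        shared=len(a & b),
        only_b=len(b - a),
        members_only_a=tuple(sorted(a - b)),
        members_shared=tuple(sorted(a & b)),
        members_only_b=tuple(sorted(b - a)),
    )


@dataclass
class QCSurfaces:
    """Deterministic data behind the standard QC figures."""

    volcano: pd.DataFrame
    linkage: np.ndarray
    leaf_order: list[str]
    ratio_matrix: pd.DataFrame
    pca_scores: pd.DataFrame
    pca_explained_variance_ratio: np.ndarray
    sample_summaries: pd.DataFrame


def qc_surfaces(
    table: ProteinQuantTable,
    classified: pd.DataFrame,
    n_components: int | None = None,
) -> QCSurfaces:
    """Volcano table, sample clustering, PCA and per-sample summaries.

    Clustering runs on log2 ratios (each sample over the protein's
    control-group mean) of the differential proteins only, with
    correlation distance and average linkage; PCA runs on centered log2
    values of all fully observed quantified proteins, samples as
    observations.  Everything is a pure function of its inputs.
    """
    volcano = pd.DataFrame(
        {
            "log2_fc": classified["log2_fc"],
            "neg_log10_p": -np.log10(classified["p_value"]),
            "call": classified["call"],
        },
        index=classified.index,
    )

    diff_accs = classified.index[classified["call"].isin([CALL_UP, CALL_DOWN])]
    if len(diff_accs) < 2 or table.data.shape[1] < 2:
        raise ValueError("clustering requires >= 2 differential proteins and >= 2 samples")
    ctrl_cols = table.group_columns(GROUP_CONTROL)
    sub = table.data.loc[diff_accs].dropna(axis=0, how="any")
    ctrl_mean = sub[ctrl_cols].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.log2(sub.div(ctrl_mean, axis=0))
    X = ratios.to_numpy().T  # samples x proteins
    if np.allclose(X.std(axis=1), 0):
        raise ValueError("constant matrix: correlation distance undefined")
    dist = pdist(X, metric="correlation")
    Z = _average_linkage(dist)
    order = [ratios.columns[i] for i in leaves_list(Z)]

    pca_scores, evr = compute_pca(table, n_components)

    logvals = np.log2(table.data)
    summaries = logvals.describe().T
    summaries.index.name = "sample"

    return QCSurfaces(
        volcano=volcano,
        linkage=Z,
        leaf_order=order,
        ratio_matrix=ratios,
        pca_scores=pca_scores,
        pca_explained_variance_ratio=evr,
        sample_summaries=summaries,
    )


def compute_pca(table: ProteinQuantTable, n_components: int | None = None):
    """PCA of samples over centered log2 abundances of fully observed proteins.

    Returns (scores DataFrame indexed by sample, explained variance ratios).
    """
    full = np.log2(table.data.dropna(axis=0, how="any"))
    Xp = full.to_numpy().T  # samples x proteins
    Xp = Xp - Xp.mean(axis=0)
    k = n_components or min(Xp.shape[0], 10)
    pca = PCA(n_components=min(k, min(Xp.shape) - 1 if min(Xp.shape) > 1 else 1), svd_solver="full")
    scores = pca.fit_transform(Xp)
    frame = pd.DataFrame(
        scores, index=full.columns, columns=[f"PC{i+1}" for i in range(scores.shape[1])]
    )
    return frame, pca.explained_variance_ratio_


def plot_qc(qc: QCSurfaces, outdir, prefix: str = "") -> list[str]:
    """Render volcano, heatmap and PCA figures to PNG files."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path
    from scipy.cluster.hierarchy import dendrogram

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    fig, ax = plt.subplots(figsize=(5, 4))
    colors = {CALL_UP: "tab:red", CALL_DOWN: "tab:green"}
    for call, sub in qc.volcano.groupby("call"):
        ax.scatter(sub["log2_fc"], sub["neg_log10_p"], s=6,
                   c=colors.get(call, "lightgray"), label=call)
    ax.axhline(-np.log10(0.05), color="red", lw=0.8)
    for x in (np.log2(DEFAULT_UP_FC), np.log2(DEFAULT_DOWN_FC)):
        ax.axvline(x, color="blue", lw=0.8)
    ax.set_xlabel("log2 fold change (glaucoma/control)")
    ax.set_ylabel("-log10 p-value")
    ax.legend(fontsize=7)
    path = outdir / f"{prefix}volcano.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(str(path))

    fig, (ax1, ax2) = plt.subplots(
        2, 1, figsize=(6, 6), gridspec_kw={"height_ratios": [1, 3]}
    )
    dendrogram(qc.linkage, labels=list(qc.ratio_matrix.columns), ax=ax1, leaf_font_size=6)
    mat = qc.ratio_matrix[qc.leaf_order]
    im = ax2.imshow(mat.to_numpy(), aspect="auto", cmap="RdYlGn_r")
    ax2.set_xticks(range(len(qc.leaf_order)), qc.leaf_order, rotation=90, fontsize=6)
    ax2.set_yticks([])
    fig.colorbar(im, ax=ax2, shrink=0.6)
    path = outdir / f"{prefix}heatmap.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(str(path))

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(qc.pca_scores["PC1"], qc.pca_scores.get("PC2", 0), s=12)
    for name, row in qc.pca_scores.iterrows():
        ax.annotate(name, (row["PC1"], row.get("PC2", 0)), fontsize=6)
    evr = qc.pca_explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0]*100:.1f}%)")
    if len(evr) > 1:
        ax.set_ylabel(f"PC2 ({evr[1]*100:.1f}%)")
    path = outdir / f"{prefix}pca.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(str(path))
    return written
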