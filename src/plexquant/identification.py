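"""Peptide-spectrum matching, FDR filtering and parsimonious protein inference.

The scorer is a deliberately simple, deterministic stand-in for a
commercial search engine: candidates are selected by precursor mass and
scored by the fraction of theoretical unit-charge b/y ions matched,
weighted by the matched intensity fraction.  PSMs are filtered to a
target peptide-level FDR with a linear discriminant over the score
features, ranked against reversed-sequence decoys; proteins are then
inferred by a minimal set cover (exact on small instances), scored by
multiplying per-peptide error probabilities, and filtered to a target
protein-level FDR the same way.
"""
from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .masses import fragment_mzs, peptide_mass, PROTON_MASS
from .spectra import SpectrumRecord
from .synthetic import DigestedPeptide, DECOY_PREFIX

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("score", "delta", "ppm_error", "missed")


@dataclass
class PeptideSpectrumMatch:
    """A candidate peptide <-> MS2 scan assignment with score features."""

    scan_id: int
    peptide: str
    parents: tuple[str, ...]
    is_decoy: bool
    score: float
    delta: float
    ppm_error: float
    missed: int
    posterior_correct: float | None = None
    is_correct: bool | None = None  # ground-truth flag on simulated data

    @property
    def features(self) -> np.ndarray:
        return np.array([self.score, self.delta, self.ppm_error, self.missed], dtype=float)


class PeptideIndex:
    """Target+decoy peptide database indexed by precursor (neutral) mass."""

    def __init__(self, peptides: dict[str, DigestedPeptide]):
        entries = sorted(peptides.values(), key=lambda p: p.sequence)
        self.entries = entries
        self.masses = np.array([peptide_mass(p.sequence) for p in entries])
        order = np.argsort(self.masses, kind="stable")
        self.masses = self.masses[order]
        self.entries = [entries[i] for i in order]

    @classmethod
    def from_proteins(
        cls,
        targets: list[tuple[str, str]],
        decoys: list[tuple[str, str]],
        max_missed: int = 2,
        min_length: int = 6,
    ) -> "PeptideIndex":
        from .synthetic import digest_proteome

        return cls(digest_proteome(list(targets) + list(decoys), max_missed, min_length))

    def candidates(self, neutral_mass: float, tol_ppm: float) -> list[DigestedPeptide]:
        tol = neutral_mass * tol_ppm * 1e-6
        lo = np.searchsorted(self.masses, neutral_mass - tol, side="left")
        hi = np.searchsorted(self.masses, neutral_mass + tol, side="right")
        return self.entries[lo:hi]


def is_decoy_parents(parents: tuple[str, ...]) -> bool:
    """A match counts as a decoy only if every parent is a decoy."""
    return all(p.startswith(DECOY_PREFIX) for p in parents)


def _match_score(spectrum: SpectrumRecord, theo_mz: np.ndarray, fragment_tol: float) -> float:
    if len(theo_mz) == 0 or spectrum.n_peaks == 0:
        return 0.0
    obs = spectrum.mz
    idx = np.searchsorted(obs, theo_mz)
    idx_lo = np.clip(idx - 1, 0, len(obs) - 1)
    idx_hi = np.clip(idx, 0, len(obs) - 1)
    d_lo = np.abs(obs[idx_lo] - theo_mz)
    d_hi = np.abs(obs[idx_hi] - theo_mz)
    nearest = np.where(d_lo <= d_hi, idx_lo, idx_hi)
    hit = np.abs(obs[nearest] - theo_mz) <= fragment_tol
    if not hit.any():
        return 0.0
    frac_ions = hit.sum() / len(theo_mz)
    matched_peaks = np.unique(nearest[hit])
    frac_int = spectrum.intensity[matched_peaks].sum() / max(spectrum.intensity.sum(), 1e-12)
    return float(frac_ions * frac_int)


def score_psms(
    spectra: list[SpectrumRecord],
    index: PeptideIndex,
    precursor_tol_ppm: float = 20.0,
    fragment_tol: float = 0.8,
) -> list[PeptideSpectrumMatch]:
    """Score every MS2 scan against the indexed database.

    Emits the best-scoring candidate within precursor tolerance per
    scan; scans with no candidate in tolerance yield no PSM (the count
    is logged).  Ties break deterministically: decoy-last, then
    lexicographic peptide.
    """
    psms: list[PeptideSpectrumMatch] = []
    n_unmatched = 0
    for spec in spectra:
        if spec.ms_level != 2:
            continue
        prec = spec.precursor
        neutral = (prec.mz - PROTON_MASS) * prec.charge
        cands = index.candidates(neutral, precursor_tol_ppm)
        if not cands:
            n_unmatched += 1
            continue
        scored = []
        for cand in cands:
            s = _match_score(spec, fragment_mzs(cand.sequence), fragment_tol)
            scored.append((s, cand))
        scored.sort(key=lambda t: (-t[0], is_decoy_parents(t[1].parents), t[1].sequence))
        best_score, best = scored[0]
        runner_up = scored[1][0] if len(scored) > 1 else 0.0
        theo_mass = peptide_mass(best.sequence)
        truth = spec.annotations.get("peptide")
        psms.append(
            PeptideSpectrumMatch(
                scan_id=spec.scan_id,
                peptide=best.sequence,
                parents=best.parents,
                is_decoy=is_decoy_parents(best.parents),
                score=best_score,
                delta=best_score - runner_up,
                ppm_error=(neutral - theo_mass) / theo_mass * 1e6,
                missed=best.missed_cleavages,
                is_correct=None if truth is None else (truth == best.sequence),
            )
        )
    if n_unmatched:
        logger.info("%d MS2 scans had no candidate within tolerance", n_unmatched)
    return psms


def _local_posterior(is_target: np.ndarray, window: int = 81) -> np.ndarray:
    """Local target/decoy ratio estimate of P(correct) along the ranked axis.

    Within a sliding window, decoys estimate the number of incorrect
    targets, so P(correct | target) ~= 1 - decoys/targets, clipped to
    [0, 1] and made monotone non-increasing down the ranking.
    """
    n = len(is_target)
    w = min(window, n)
    half = w // 2
    cum_t = np.concatenate([[0], np.cumsum(is_target)])
    post = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        t = cum_t[hi] - cum_t[lo]
        d = (hi - lo) - t
        post[i] = 1.0 - d / t if t > 0 else 0.0
    post = np.clip(post, 0.0, 1.0)
    return np.minimum.accumulate(post)


def discriminant_filter(
    psms: list[PeptideSpectrumMatch],
    fdr_target: float = 0.01,
    plus_one: bool = False,
    posterior_window: int = 81,
) -> list[PeptideSpectrumMatch]:
    """Filter PSMs to a target decoy-estimated FDR via a linear discriminant.

    A two-class linear discriminant (targets vs decoys) over the
    standardized feature vector gives one scalar per PSM; PSMs are
    ranked by it and the accepted set is the largest score-threshold set
    whose estimated FDR = decoys/targets (optionally (decoys+1)/targets)
    is at or below ``fdr_target``.  Accepted PSMs get
    ``posterior_correct`` from the local target/decoy ratio along the
    discriminant axis.  Lowering ``fdr_target`` never adds PSMs.
    """
    if not psms:
        return []
    is_decoy = np.array([p.is_decoy for p in psms])
    if not (~is_decoy).any():
        return []
    X = np.array([p.features for p in psms])
    if not is_decoy.any():
        warnings.warn("no decoy PSMs: estimated FDR is 0; accepting all targets")
        for p in psms:
            p.posterior_correct = 1.0
        return list(psms)

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    if is_decoy.sum() < 5 or keep.sum() == 0:
        # too few decoys to fit a discriminant; rank by raw match score
        axis = X[:, 0]
    else:
        Xs = (X[:, keep] - mu[keep]) / sd[keep]
        lda = LinearDiscriminantAnalysis()
        lda.fit(Xs, (~is_decoy).astype(int))
        axis = lda.decision_function(Xs)

    order = sorted(
        range(len(psms)),
        key=lambda i: (-axis[i], is_decoy[i], psms[i].scan_id, psms[i].peptide),
    )
    ranked_decoy = is_decoy[order]
    cum_d = np.cumsum(ranked_decoy)
    cum_t = np.cumsum(~ranked_decoy)
    num = cum_d + 1 if plus_one else cum_d
    fdr = num / np.maximum(cum_t, 1)
    ok = np.nonzero(fdr <= fdr_target)[0]
    if len(ok) == 0:
        return []
    cutoff = ok[-1]

    posterior = _local_posterior(~ranked_decoy, posterior_window)
    accepted = []
    for rank in range(cutoff + 1):
        p = psms[order[rank]]
        p.posterior_correct = float(posterior[rank])
        accepted.append(p)
    return accepted


@dataclass
class ProteinGroup:
    """A set of indistinguishable proteins and the peptides assigned to it."""

    representative: str
    members: tuple[str, ...]
    peptides: tuple[str, ...]
    psms: tuple[PeptideSpectrumMatch, ...] = ()
    protein_score: float | None = None  # probability all support is wrong; lower = better
    is_decoy: bool = False


def _greedy_cover_order(
    candidates: list[tuple[str, frozenset]],
    universe: frozenset,
    restrict: set[str] | None = None,
) -> list[str]:
    """Greedy cover over (representative -> peptide set); deterministic ties.

    Ties break by more newly covered peptides, then more total peptides,
    then lexicographic representative.
    """
    pool = {rep: peps for rep, peps in candidates if restrict is None or rep in restrict}
    uncovered = set(universe)
    selected: list[str] = []
    while uncovered:
        best = min(
            pool.items(),
            key=lambda kv: (-len(kv[1] & uncovered), -len(kv[1]), kv[0]),
        )
        rep, peps = best
        if not peps & uncovered:
            break
        selected.append(rep)
        uncovered -= peps
        del pool[rep]
    return selected


def _exact_min_cover(sets: list[frozenset], universe: frozenset) -> list[int] | None:
    """Smallest subfamily covering the universe, by exhaustive search.

    Deterministic: smallest size first, then lexicographic index order.
    Intended for instances with at most ~15 candidate sets.
    """
    for size in range(1, len(sets) + 1):
        for combo in itertools.combinations(range(len(sets)), size):
            covered: set = set()
            for i in combo:
                covered |= sets[i]
            if covered >= universe:
                return list(combo)
    return None


def infer_proteins(accepted: list[PeptideSpectrumMatch], exact_limit: int = 15) -> list[ProteinGroup]:
    """Explain all accepted peptides with the least number of proteins.

    Proteins with identical peptide sets merge into one group
    (representative = first accession, decoys sorting last).  Groups are
    selected greedily by coverage; on instances with at most
    ``exact_limit`` candidate groups the exact minimal cover is computed
    and used whenever it is smaller than the greedy one.  Each peptide
    is assigned to the earliest-selected group that covers it, so groups
    partition the accepted peptides.
    """
    pep_parents: dict[str, tuple[str, ...]] = {}
    pep_psms: dict[str, list[PeptideSpectrumMatch]] = {}
    for psm in accepted:
        pep_parents.setdefault(psm.peptide, psm.parents)
        pep_psms.setdefault(psm.peptide, []).append(psm)
    if not pep_parents:
        return []

    prot_peps: dict[str, set] = {}
    for pep, parents in pep_parents.items():
        for acc in parents:
            prot_peps.setdefault(acc, set()).add(pep)

    # merge indistinguishable proteins (identical peptide sets)
    by_set: dict[frozenset, list[str]] = {}
    for acc, peps in prot_peps.items():
        by_set.setdefault(frozenset(peps), []).append(acc)
    groups_raw: list[tuple[str, tuple[str, ...], frozenset]] = []
    for peps, accs in by_set.items():
        accs.sort(key=lambda a: (a.startswith(DECOY_PREFIX), a))
        groups_raw.append((accs[0], tuple(accs), peps))
    groups_raw.sort(key=lambda g: g[0])

    universe = frozenset(pep_parents)
    candidates = [(rep, peps) for rep, _, peps in groups_raw]
    selected = _greedy_cover_order(candidates, universe)

    if len(groups_raw) <= exact_limit:
        sets = [peps for _, peps in candidates]
        exact = _exact_min_cover(sets, universe)
        if exact is not None and len(exact) < len(selected):
            chosen = {candidates[i][0] for i in exact}
            selected = _greedy_cover_order(candidates, universe, restrict=chosen)

    by_rep = {rep: (members, peps) for rep, members, peps in groups_raw}
    assigned: dict[str, str] = {}
    for rep in selected:
        for pep in sorted(by_rep[rep][1]):
            assigned.setdefault(pep, rep)

    out = []
    for rep in selected:
        members = by_rep[rep][0]
        peps = tuple(sorted(p for p, r in assigned.items() if r == rep))
        psms = tuple(ps for pep in peps for ps in pep_psms[pep])
        out.append(
            ProteinGroup(
                representative=rep,
                members=members,
                peptides=peps,
                psms=psms,
                is_decoy=all(m.startswith(DECOY_PREFIX) for m in members),
            )
        )
    return out


def rank_proteins(groups: list[ProteinGroup], fdr_target: float = 0.01, plus_one: bool = False) -> list[ProteinGroup]:
    """Score, rank and FDR-filter protein groups.

    The protein score is the product over assigned peptides of
    (1 - posterior_correct) — the probability that every piece of
    support is wrong — taking each peptide's best PSM posterior.  Groups
    rank ascending by score and the accepted set is the largest prefix
    whose decoy-estimated FDR is at or below ``fdr_target``.
    """
    for g in groups:
        if not g.peptides:
            raise ValueError(f"protein group {g.representative} has no assigned peptides")
        pep_post = {}
        for psm in g.psms:
            if psm.posterior_correct is None:
                raise ValueError(f"PSM {psm.scan_id} lacks posterior_correct; run discriminant_filter first")
            pep_post[psm.peptide] = max(pep_post.get(psm.peptide, 0.0), psm.posterior_correct)
        score = 1.0
        for pep in g.peptides:
            score *= 1.0 - pep_post[pep]
        g.protein_score = score

    ranked = sorted(groups, key=lambda g: (g.protein_score, g.is_decoy, g.representative))
    is_decoy = np.array([g.is_decoy for g in ranked])
    if len(ranked) == 0:
        return []
    cum_d = np.cumsum(is_decoy)
    cum_t = np.cumsum(~is_decoy)
    num = cum_d + 1 if plus_one else cum_d
    fdr = num / np.maximum(cum_t, 1)
    ok = np.nonzero(fdr <= fdr_target)[0]
    if len(ok) == 0:
        return []
    return ranked[: ok[-1] + 1]


def psms_from_frame(df: pd.DataFrame) -> list[PeptideSpectrumMatch]:
    """Build PSM objects from a feature table (e.g. simulate_psm_features).

    Required columns: score, delta, ppm_error, missed, is_decoy;
    optional: is_correct, scan_id, peptide.
    """
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        decoy = bool(row.is_decoy)
        acc = ("rev_SIM",) if decoy else ("SIM",)
        out.append(
            PeptideSpectrumMatch(
                scan_id=int(getattr(row, "scan_id", i)),
                peptide=str(getattr(row, "peptide", f"PEP{i}")),
                parents=acc,
                is_decoy=decoy,
                score=float(row.score),
                delta=float(row.delta),
                ppm_error=float(row.ppm_error),
                missed=int(row.missed),
                is_correct=bool(row.is_correct) if hasattr(row, "is_correct") else None,
            )
        )
    return out


def psms_to_frame(psms: list[PeptideSpectrumMatch]) -> pd.DataFrame:
    """PSM list as a tidy table (one row per PSM)."""
    return pd.DataFrame(
        {
            "scan_id": [p.scan_id for p in psms],
            "peptide": [p.peptide for p in psms],
            "parents": [";".join(p.parents) for p in psms],
            "is_decoy": [p.is_decoy for p in psms],
            "score": [p.score for p in psms],
            "delta": [p.delta for p in psms],
            "ppm_error": [p.ppm_error for p in psms],
            "missed": [p.missed for p in psms],
            "posterior_correct": [p.posterior_correct for p in psms],
        }
    )
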