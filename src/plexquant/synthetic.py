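"""Synthetic ground truth and simulated 10-plex MS1/MS2/MS3 spectra.

Everything downstream of the mass spectrometer is testable against this
module: it generates a proteome with known differential structure,
digests it with the combined Lys-C/trypsin rule, builds reversed decoys,
and emits spectra whose reporter regions encode the true per-channel
abundances mixed through an isotope-impurity matrix, contaminated by
co-isolation interference and additive noise.  All outputs are pure
functions of (parameters, seed).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .channels import ImpurityMatrix, default_channels
from .design import GROUP_GLAUCOMA, Plex, PlexDesign, default_design
from .masses import fragment_mzs, peptide_mass, PROTON_MASS, C13_C12_DELTA
from .spectra import Precursor, SpectrumRecord

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
# mild K/R enrichment so random proteins digest into tryptic-sized peptides
_AA_WEIGHTS = np.array(
    [1.0, 0.6, 1.2, 1.4, 0.9, 1.5, 0.6, 1.1, 1.4, 2.0, 0.5, 0.9, 1.0, 1.0, 1.3, 1.6, 1.2, 1.3, 0.3, 0.7]
)
_AA_WEIGHTS = _AA_WEIGHTS / _AA_WEIGHTS.sum()

DECOY_PREFIX = "rev_"


@dataclass
class GroundTruth:
    """The simulated biological truth behind one study.

    ``abundance`` holds strictly positive relative abundances, proteins
    as rows and one column per biological sample (subject); the same
    protein-level fold change applies in every tissue of the design.
    """

    proteins: list[tuple[str, str]]
    abundance: pd.DataFrame
    sample_groups: pd.Series
    sample_tissues: pd.Series
    is_differential: np.ndarray
    true_fc: np.ndarray
    base_abundance: np.ndarray

    @property
    def accessions(self) -> list[str]:
        return [acc for acc, _ in self.proteins]


@dataclass(frozen=True)
class DigestedPeptide:
    sequence: str
    parents: tuple[str, ...]
    missed_cleavages: int


def generate_ground_truth(
    n_proteins: int,
    frac_differential: float = 0.1,
    fc_range: tuple[float, float] = (1.5, 3.0),
    design: PlexDesign | None = None,
    biological_cv: float = 0.2,
    seed: int = 0,
    median_abundance: float = 100.0,
    abundance_sigma: float = 1.0,
    length_range: tuple[int, int] = (60, 240),
) -> GroundTruth:
    """Draw a proteome with a known differential subset.

    A fraction ``frac_differential`` of proteins (rounded) receives a
    glaucoma/control group-mean ratio drawn uniformly from ``fc_range``,
    with up- or down-regulation chosen with equal probability (down is
    the reciprocal).  Per-subject abundances are log-normal around the
    group mean with coefficient of variation ``biological_cv``; the
    multiplicative noise has unit mean so group means are unbiased on
    the raw scale.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    if not 0 <= frac_differential <= 1:
        raise ValueError("frac_differential must be in [0, 1]")
    low, high = fc_range
    if low <= 0 or high <= 0 or low > high:
        raise ValueError("fc_range bounds must be positive with low <= high")
    if biological_cv < 0:
        raise ValueError("biological_cv must be >= 0")
    design = design if design is not None else default_design()
    rng = np.random.default_rng(seed)

    lengths = rng.integers(length_range[0], length_range[1] + 1, size=n_proteins)
    proteins = []
    for i, L in enumerate(lengths):
        seq = "".join(rng.choice(_AMINO_ACIDS, size=L, p=_AA_WEIGHTS))
        proteins.append((f"SYN{i:05d}", seq))

    base = median_abundance * rng.lognormal(0.0, abundance_sigma, size=n_proteins)

    n_diff = int(round(n_proteins * frac_differential))
    flagged = rng.choice(n_proteins, size=n_diff, replace=False)
    is_differential = np.zeros(n_proteins, dtype=bool)
    is_differential[flagged] = True
    true_fc = np.ones(n_proteins)
    if n_diff:
        magnitude = rng.uniform(low, high, size=n_diff)
        up = rng.random(n_diff) < 0.5
        true_fc[flagged] = np.where(up, magnitude, 1.0 / magnitude)

    samples = design.samples()
    sample_ids = [c.subject for c in samples]
    groups = pd.Series([c.group for c in samples], index=sample_ids)
    tissues = pd.Series(
        [p.tissue for p in design.plexes for _ in p.channels], index=sample_ids
    )

    sigma = np.sqrt(np.log1p(biological_cv**2))
    cols = {}
    for c in samples:
        mean = base * np.where(c.group == GROUP_GLAUCOMA, true_fc, 1.0)
        noise = rng.lognormal(-0.5 * sigma**2, sigma, size=n_proteins) if sigma > 0 else 1.0
        cols[c.subject] = mean * noise
    abundance = pd.DataFrame(cols, index=[acc for acc, _ in proteins])

    return GroundTruth(
        proteins=proteins,
        abundance=abundance,
        sample_groups=groups,
        sample_tissues=tissues,
        is_differential=is_differential,
        true_fc=true_fc,
        base_abundance=base,
    )


def _cleavage_fragments(sequence: str) -> list[str]:
    """Split at the C-terminal side of K/R unless the next residue is P."""
    cuts = [0]
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR" and sequence[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(sequence))
    return [sequence[cuts[k]:cuts[k + 1]] for k in range(len(cuts) - 1)]


def digest_proteome(
    proteins: list[tuple[str, str]],
    max_missed: int = 2,
    min_length: int = 6,
) -> dict[str, DigestedPeptide]:
    """In-silico Lys-C + trypsin digest with missed cleavages.

    Cleaves C-terminally to K/R, not before P.  Returns peptides keyed
    by sequence; a peptide shared between proteins maps to all parents,
    and ``missed_cleavages`` records the smallest count over its
    occurrences.  Empty sequences are skipped with a warning.
    """
    out: dict[str, dict] = {}
    for acc, seq in proteins:
        if not seq:
            warnings.warn(f"protein {acc} has an empty sequence; skipped")
            continue
        seq = seq.upper()
        frags = _cleavage_fragments(seq)
        for start in range(len(frags)):
            for n_miss in range(min(max_missed, len(frags) - start - 1) + 1):
                pep = "".join(frags[start:start + n_miss + 1])
                if len(pep) < min_length:
                    continue
                rec = out.setdefault(pep, {"parents": set(), "missed": n_miss})
                rec["parents"].add(acc)
                rec["missed"] = min(rec["missed"], n_miss)
    return {
        pep: DigestedPeptide(pep, tuple(sorted(rec["parents"])), rec["missed"])
        for pep, rec in out.items()
    }


def make_decoy_database(targets: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """One reversed-sequence decoy per target, accession-prefixed ``rev_``.

    A palindromic target yields a decoy identical to it; the collision
    is emitted anyway and handled downstream (a peptide found in any
    target parent is never counted as a decoy match).
    """
    if not targets:
        raise ValueError("target list must be non-empty")
    return [(DECOY_PREFIX + acc, seq[::-1]) for acc, seq in targets]


def _draw_interference(spec, rng: np.random.Generator) -> float:
    if callable(spec):
        f = float(spec(rng))
    elif isinstance(spec, tuple) and spec and spec[0] == "beta":
        f = float(rng.beta(spec[1], spec[2]))
    else:
        f = float(spec)
    if not 0 <= f < 1:
        raise ValueError(f"interference fraction must be in [0, 1), got {f}")
    return f


_ENVELOPE_REL = np.array([1.0, 0.6, 0.25, 0.08])  # crude averagine-ish envelope


def simulate_plex_spectra(
    truth: GroundTruth,
    plex: Plex,
    impurity: ImpurityMatrix | None = None,
    interference=("beta", 2.0, 18.0),
    noise_baseline: float = 1.0,
    noise_sd: float = 0.0,
    reporter_yield: float = 50.0,
    psm_depth: float = 3.0,
    max_missed: int = 2,
    min_length: int = 6,
    seed: int = 0,
    peptides: dict[str, DigestedPeptide] | None = None,
    first_scan_id: int = 1,
) -> list[SpectrumRecord]:
    """Simulate the SPS-MS3 acquisition of one 10-plex experiment.

    For every sampled peptide the stream carries an MS1 survey scan
    (isotopic envelope plus, at the drawn interference fraction, a
    contaminant peak inside the 0.5 Da isolation window), an MS2
    fragment scan of unit-charge b/y ions, and an MS3 reporter scan.
    True reporter intensities are proportional to the generating
    protein's per-channel abundance, mixed through the impurity matrix;
    interference adds contaminant reporter signal spread uniformly over
    the ten channels, and Gaussian noise of sd ``noise_sd`` is added on
    top.  Every peak carries the ``noise_baseline`` noise estimate.

    The number of PSMs sampled per protein is ``1 + Poisson(lam)`` with
    ``lam`` proportional (via ``psm_depth``) to log10 abundance, a crude
    detectability model; each PSM receives an equal share of the
    protein's total reporter yield so that, with identity impurity and
    zero noise/interference, per-channel totals over the whole stream
    equal ``reporter_yield`` times the channel's summed abundance.

    ``interference`` may be a constant fraction, a ``("beta", a, b)``
    tuple, or a callable ``rng -> fraction``.
    """
    rng = np.random.default_rng(seed)
    channels = default_channels()
    impurity = impurity if impurity is not None else ImpurityMatrix.default()
    M = impurity.matrix
    if peptides is None:
        peptides = digest_proteome(truth.proteins, max_missed=max_missed, min_length=min_length)
    by_protein: dict[str, list[str]] = {}
    for pep in peptides.values():
        for acc in pep.parents:
            by_protein.setdefault(acc, []).append(pep.sequence)
    for seqs in by_protein.values():
        seqs.sort()

    sample_ids = [c.subject for c in plex.channels]
    A = truth.abundance.loc[:, sample_ids].to_numpy()
    reporter_mzs = np.array([c.mz for c in channels])

    records: list[SpectrumRecord] = []
    scan_id = first_scan_id
    for p_idx, acc in enumerate(truth.abundance.index):
        peps = by_protein.get(acc)
        if not peps:
            continue
        lam = psm_depth * max(np.log10(1.0 + truth.base_abundance[p_idx]), 0.0)
        n_psm = 1 + int(rng.poisson(lam))
        chosen = rng.choice(peps, size=n_psm, replace=True)
        true_per_psm = reporter_yield * A[p_idx] / n_psm
        for pep_seq in chosen:
            z = int(rng.choice([2, 3]))
            mz0 = (peptide_mass(pep_seq) + z * PROTON_MASS) / z
            f = _draw_interference(interference, rng)

            # MS1 survey scan: isotopic envelope + optional contaminant
            env_mz = mz0 + np.arange(4) * C13_C12_DELTA / z
            prec_int = float(true_per_psm.sum()) + 1e-9
            env_int = _ENVELOPE_REL * prec_int
            ms1_mz, ms1_int = list(env_mz), list(env_int)
            if f > 0:
                # only the monoisotopic peak sits inside the +-0.25 window
                ms1_mz.append(mz0 + 0.11)
                ms1_int.append(f / (1.0 - f) * env_int[0])
            order = np.argsort(ms1_mz)
            ms1_int_arr = np.asarray(ms1_int)[order]
            if noise_sd > 0:
                ms1_int_arr = np.clip(ms1_int_arr + rng.normal(0, noise_sd, len(ms1_int_arr)), 0, None)
            ms1 = SpectrumRecord(
                scan_id, 1, np.asarray(ms1_mz)[order], ms1_int_arr,
                np.full(len(ms1_mz), noise_baseline),
            )

            # MS2 fragment scan
            frag_mz = fragment_mzs(pep_seq)
            frag_int = 100.0 * rng.lognormal(0.0, 0.3, size=len(frag_mz))
            if noise_sd > 0:
                frag_int = np.clip(frag_int + rng.normal(0, noise_sd, len(frag_int)), 1e-3, None)
            ms2 = SpectrumRecord(
                scan_id + 1, 2, frag_mz, frag_int, np.full(len(frag_mz), noise_baseline),
                precursor=Precursor(mz0, z, 0.25, scan_id),
                annotations={"peptide": pep_seq, "interference": f},
            )

            # MS3 reporter scan
            observed = M @ true_per_psm
            if f > 0:
                observed = observed + (f / (1.0 - f)) * true_per_psm.sum() / 10.0
            if noise_sd > 0:
                observed = np.clip(observed + rng.normal(0, noise_sd, 10), 0, None)
            jitter = rng.uniform(-0.0004, 0.0004, size=10)
            ms3 = SpectrumRecord(
                scan_id + 2, 3, reporter_mzs + jitter, observed,
                np.full(10, noise_baseline),
                precursor=Precursor(mz0, z, 1.25, scan_id + 1),
                annotations={
                    "peptide": pep_seq,
                    "proteins": peptides[pep_seq].parents,
                    "interference": f,
                    "true_intensity": true_per_psm.copy(),
                    "plex_id": plex.plex_id,
                },
            )
            records.extend([ms1, ms2, ms3])
            scan_id += 3
    return records


def simulate_psm_features(
    n_correct: int,
    n_incorrect: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw PSM score features with known correctness for FDR studies.

    Correct matches are always targets with well-separated score/delta
    distributions; incorrect matches draw from a common poor-score
    distribution and land on a target or a reversed-sequence decoy with
    equal probability, the symmetry the decoy FDR estimate relies on.
    Columns: score, delta, ppm_error, missed, is_decoy, is_correct.
    """
    rng = np.random.default_rng(seed)

    def block(n: int, correct: bool) -> pd.DataFrame:
        if correct:
            score = np.clip(rng.normal(0.55, 0.12, n), 0.02, 1.0)
            delta = np.abs(rng.normal(0.25, 0.08, n))
            ppm = rng.normal(0.0, 2.5, n)
            missed = rng.poisson(0.25, n)
            decoy = np.zeros(n, dtype=bool)
        else:
            score = np.clip(rng.normal(0.22, 0.08, n), 0.0, 1.0)
            delta = np.abs(rng.normal(0.04, 0.03, n))
            ppm = np.clip(rng.normal(0.0, 7.0, n), -20, 20)
            missed = rng.poisson(0.8, n)
            decoy = rng.random(n) < 0.5
        return pd.DataFrame(
            {"score": score, "delta": delta, "ppm_error": ppm,
             "missed": missed, "is_decoy": decoy, "is_correct": correct}
        )

    df = pd.concat([block(n_correct, True), block(n_incorrect, False)], ignore_index=True)
    return df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
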