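# Methods

This note records the models, parameter choices and numerical decisions
behind `plexquant`, in the order data flows through the pipeline.

## Study design

The design object encodes four 10-plex TMT experiments: two per tissue
(retina, vitreous), each with 5 control subjects on channels 126–128C and
5 glaucoma subjects on 129N–131. Subjects are unique within a tissue, so
a tissue contributes 20 biological replicates split across two plexes.
There is no bridge/reference channel in this layout; that constrains the
cross-plex merge (below).

## Synthetic ground truth

`generate_ground_truth` draws a proteome of random amino-acid sequences
(60–240 residues, mildly K/R-enriched so tryptic peptides have realistic
lengths) with log-normal base abundances (median 100 arbitrary units,
σ = 1 in log space). A fraction of proteins (default 10%) is flagged
differential; each flagged protein receives a glaucoma/control group-mean
ratio drawn uniformly from the configured range (default 1.5–3.0), with
up- or down-regulation equally likely (down = reciprocal). Per-subject
abundances are the group mean times log-normal noise with a stated
coefficient of variation (default 20%); the noise has unit mean so that
raw-scale group means, and hence fold-change estimates, are unbiased.
Non-differential proteins have true fold change exactly 1. The same
protein-level truth applies in both tissues, which makes the tissue
overlap of calls a pure replication readout.

The default study size (200 proteins) keeps a full two-tissue,
four-plex run in single-digit seconds; every generator output is a pure
function of its parameters and seed.

## Digestion, decoys, masses

Digestion follows the combined Lys-C + trypsin rule — cleave C-terminally
to K or R, not before P — with up to 2 missed cleavages and a minimum
peptide length of 6 (common practice defaults). Shared peptides map to
all parents. Decoys are whole-protein sequence reversals with a fixed
`rev_` accession prefix; a palindromic sequence yields a decoy identical
to its target, which is emitted anyway and neutralized downstream (a
peptide with any target parent never counts as a decoy match).

All peptides carry fixed carbamidomethyl-Cys and TMT tags on the
N-terminus and every Lys (229.162932 Da each); residue masses come from
pyteomics. The fragmentation model shared by the simulator and the
scorer is unit-charge b/y ions only — deliberately minimal, since a
faithful commercial search engine is out of scope and a deterministic,
analyzable scorer is the point.

## Spectrum simulation

Each sampled peptide contributes an MS1/MS2/MS3 triple:

- **MS1**: a four-peak isotopic envelope (spacing 1.00335/z) plus, at the
  drawn interference fraction *f*, one contaminant peak inside the 0.5 Da
  isolation window with intensity f/(1−f) times the in-window precursor
  signal, so that isolation specificity is 1 − f by construction.
- **MS2**: the b/y ions with log-normal intensity variation, linked to
  the MS1 scan.
- **MS3**: ten reporter peaks at the theoretical channel m/z values
  (± ≤0.4 mTh jitter, inside the 3 mTh extraction window). True channel
  intensities are proportional to the generating protein's per-channel
  abundance; they are mixed through the impurity matrix, interference
  adds f/(1−f) of the target total spread uniformly over the ten
  channels (a worst-case ratio-compression model and the simplest
  defensible one), and Gaussian noise (sd default 2) is added. Every peak
  carries a constant noise estimate (default 1), so S/N is defined.

PSM depth per protein is 1 + Poisson(λ) with λ proportional to log10
abundance — a crude detectability model that avoids simulating
chromatography. Each PSM receives an equal share of its protein's total
reporter yield (default 50 × abundance), so that with identity impurity
and no noise/interference the per-channel totals over the stream equal
yield × summed channel abundance exactly; this conservation property is
what makes the quantification chain testable end to end.

Interference fractions default to Beta(2, 18) (mean 0.1, occasional
values above the 0.25 that fails the specificity filter). The magnitudes
of noise and interference are simulator choices, not literature values.

## Reporter channels and the impurity matrix

The ten reporter m/z constants are derivable from the isotopologue
composition C8H16N+ with 0–4 ¹³C and 0–1 ¹⁵N substitutions; a test
recomputes them from atomic masses. Extraction uses a 0.003 Th full
window and the closest-signal rule; an empty window contributes S/N 0
(not missing), consistent with summing total S/N over *all* channels.

Reagent lot certificates are not public, so the default leakage matrix is
a versioned fixture (`data/tmt10_impurity_v1.tsv`): 1–3% to adjacent
channel indices, up to 0.3% two away, diagonal = 1 − leakage. Real TMT10
isotope envelopes couple channels of the same ¹⁵N series (two index
positions apart) more strongly than adjacent indices; the fixture's
index-adjacent structure is a simplification and is trivially replaceable
by a lot-specific table of the same format. Correction solves
observed = M·true by nonnegative least squares (`scipy.optimize.nnls`),
which returns the exact inverse when one exists and a nonnegative
least-squares fit when noise pushes the plain inverse negative; matrices
with condition number above 1e8 are rejected by name. The identity
matrix short-circuits to an exact pass-through.

Isolation specificity is computed from the MS1 survey scan (the natural
choice; the acquisition description does not pin this down): envelope
membership is within 10 ppm of precursor m/z + k·1.00335/z, k = 0..3.
Both quantifiability gates are strict (> 200 total S/N, > 0.75
specificity), so boundary values are rejected; tests fix this behaviour.

## Identification statistics

The LDA over PSM features (match score, delta to runner-up, precursor
ppm error, missed cleavages) is the closed-form two-class discriminant on
standardized features (scikit-learn). With fewer than five decoys the
discriminant is unidentifiable and ranking falls back to the raw match
score. The accepted set is the largest threshold set with
decoys/targets ≤ the FDR target; the +1-corrected estimator
(decoys+1)/targets is available but off by default, matching the plain
reversed-sequence counting estimate. This largest-passing-set rule is
known to be slightly anti-conservative (the realized false-discovery
proportion at the 1% filter runs a few percent of its level above the
estimate in calibration studies, e.g. ~1.1% here); the calibration test
bounds it by the binomial interval rather than asserting equality.

Peptide posteriors are local target/decoy ratio estimates along the
discriminant axis (sliding window of 81, P(correct) = 1 − d/t clipped to
[0, 1], made monotone along the ranking). "Multiplying peptide
probabilities" for protein scores is read as multiplying peptide *error*
probabilities ∏(1 − pᵢ) — the probability that every piece of support is
wrong — so lower scores rank better; the alternative reading (product of
correctness probabilities) would punish well-supported proteins and
cannot produce a meaningful ranking.

Parsimony is greedy set cover with deterministic tie-breaks (most new
peptides, then most total peptides, then lexicographic accession);
proteins with identical peptide sets merge into one group, shared
peptides go to the earliest-selected group, so groups partition the
accepted peptides. On instances with ≤ 15 candidate groups an exhaustive
search replaces the greedy cover whenever it finds a smaller one, making
the small-instance result provably minimal.

On clean simulated spectra the scorer essentially never selects a decoy
(the correct peptide's fragments are all present), so the pipeline run
itself exercises the no-decoy degenerate path of the filter; the FDR
machinery is instead calibrated on simulated PSM feature sets with known
correctness, where targets and decoys genuinely overlap.

## Normalization, roll-up, aggregation

Channel equalization multiplies channel j by mean(sums)/sum_j; the
equal-sum target is the mean of the channel sums — any common constant
gives identical downstream ratios, so the choice is cosmetic but fixed
for reproducibility. A zero-sum channel is an error naming the channel.
Roll-up is an element-wise sum of each protein group's peptide rows;
proteins whose peptides all failed the filters are absent, and grand
totals are conserved.

The two plexes of a tissue are merged by internal-reference scaling:
each protein's channel values are divided by its within-plex row mean
before the 10+10 columns are concatenated. The source protocol says only
that the two experiments were "aggregated into a single report", and the
design has no bridge channel, so some such scaling is required for
cross-plex comparability under the balanced 5+5 layout; row-median and
no-op alternatives are exposed as configuration. Proteins seen in one
plex keep 10 values and 10 missing; missing values propagate as missing
into testing (never zero-imputed).

## Differential testing

Fold change is computed on the raw relative-abundance scale, the t-test
on log2 values (Student pooled-variance by default, Welch optional) —
the heatmaps are log-ratio based and log2 abundances are closer to
normal, but a raw-scale option exists since the original test scale is
not stated. Both call boundaries are inclusive (p ≤ α, FC ≥ up or
≤ down). The down threshold is 0.77 by default with 0.76 selectable: the
source protocol prints both values in different places, and the package
surfaces rather than resolves the discrepancy. No multiple-testing
correction enters the calls (matching the original raw-p procedure); a
Benjamini–Hochberg q-value column is emitted for reference only.
Proteins with fewer than 3 non-missing values per group are untestable;
identical constant groups report p = 1.

QC surfaces are deterministic data, with rendering kept separate:
volcano rows (log2 FC, −log10 p, call); sample clustering on log2
ratios to the per-protein control mean with correlation distance and
average linkage (a constant matrix is an error — the distance is
undefined); PCA of samples on centered log2 values of fully observed
proteins; per-sample distribution summaries.

## What the tests do and do not show

The simulator reproduces the *structure* of SPS-MS3 data — plex layouts,
impurity mixing, co-isolation interference, S/N-based quantification —
but not chromatography, charge-state errors, missing channels, peptide
ionization biases, or real spectral noise shapes. Passing tests
demonstrate that each stage implements its stated contract and that the
statistical machinery is calibrated under the model's assumptions; they
do not certify performance on real instrument data. The published
differential counts can be recomputed only from the journal's
supplementary per-tissue tables, which are not redistributable here; the
acceptance tests for those counts run whenever the tables are placed
under `data/supplementary/` and fail otherwise.

## Problem sizes

Default simulated studies use 200 proteins per run; calibration studies
use 20 replicate datasets of 2 000 PSMs (FDR), 20 × 1 000 proteins
(null behaviour), 5 × 400 proteins (parameter recovery), 200 random
instances (parsimony), and 1 000 random matrices (impurity round trip) —
sizes chosen so the full suite and the acceptance script each run in
well under a minute of compute while keeping binomial test bounds tight
enough to detect miscalibration.
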