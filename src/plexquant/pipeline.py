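"""End-to-end orchestration: simulate -> identify -> quantify -> roll up ->
differential -> report, with a reproducibility manifest.

Every stage writes its table under the run directory; the manifest
records the configuration, package version and SHA-256 of every output,
so a rerun with the same configuration is hash-identical.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .channels import ImpurityMatrix, TMT10_CHANNEL_NAMES
from .config import PipelineConfig
from .design import PlexDesign, default_design
from .differential import classify_differential, qc_surfaces, summarize_calls, test_table, venn_overlap
from .identification import (
    PeptideIndex, discriminant_filter, infer_proteins, psms_to_frame, rank_proteins, score_psms,
)
from .mzml_io import write_ground_truth_sidecar, write_mzml
from .reporter import filter_quantifiable, quantified_to_frame, quantify_spectra
from .rollup import aggregate_plexes, normalize_channels, rollup_proteins
from .synthetic import digest_proteome, generate_ground_truth, make_decoy_database, simulate_plex_spectra
from .tables import write_fasta, write_quant_table, write_tsv

logger = logging.getLogger(__name__)


def _stage_seed(seed: int, index: int) -> int:
    return (seed * 100003 + 7919 * (index + 1)) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: PipelineConfig,
    outdir,
    design: PlexDesign | None = None,
    write_spectra: bool = True,
) -> dict:
    """Execute the full pipeline and return the summary dictionary."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = design if design is not None else default_design(config.tissues)
    impurity = ImpurityMatrix.default()

    truth = generate_ground_truth(
        n_proteins=config.n_proteins,
        frac_differential=config.frac_differential,
        fc_range=config.fc_range,
        design=design,
        biological_cv=config.biological_cv,
        seed=_stage_seed(config.seed, 0),
    )
    targets = truth.proteins
    decoys = make_decoy_database(targets)
    write_fasta(targets + decoys, outdir / "database.fasta")
    peptides = digest_proteome(targets + decoys, config.max_missed, config.min_length)
    index = PeptideIndex(peptides)
    target_peptides = digest_proteome(targets, config.max_missed, config.min_length)

    truth_table = pd.DataFrame(
        {
            "accession": truth.accessions,
            "is_differential": truth.is_differential,
            "true_fc": truth.true_fc,
            "base_abundance": truth.base_abundance,
        }
    ).set_index("accession")
    write_tsv(truth_table, outdir / "ground_truth.tsv")

    all_spectra: dict[str, list] = {}
    scan_base = 0
    for i, plex in enumerate(design.plexes):
        spectra = simulate_plex_spectra(
            truth,
            plex,
            impurity=impurity,
            interference=config.interference,
            noise_baseline=config.noise_baseline,
            noise_sd=config.noise_sd,
            reporter_yield=config.reporter_yield,
            psm_depth=config.psm_depth,
            max_missed=config.max_missed,
            min_length=config.min_length,
            seed=_stage_seed(config.seed, i + 1),
            peptides=target_peptides,
            first_scan_id=scan_base + 1,
        )
        scan_base = spectra[-1].scan_id if spectra else scan_base
        all_spectra[plex.plex_id] = spectra
        if write_spectra:
            write_mzml(spectra, outdir / f"{plex.plex_id}.mzML")
            write_ground_truth_sidecar(spectra, outdir / f"{plex.plex_id}.truth.tsv")

    flat = [s for plex in design.plexes for s in all_spectra[plex.plex_id]]
    psms = score_psms(flat, index, config.precursor_tol_ppm, config.fragment_tol_da)
    accepted = discriminant_filter(psms, config.peptide_fdr, plus_one=config.fdr_plus_one)
    groups = infer_proteins(accepted)
    accepted_groups = rank_proteins(groups, config.protein_fdr, plus_one=config.fdr_plus_one)
    write_tsv(psms_to_frame(accepted), outdir / "psms_accepted.tsv", index=False)

    group_frame = pd.DataFrame(
        {
            "representative": [g.representative for g in accepted_groups],
            "members": [";".join(g.members) for g in accepted_groups],
            "n_peptides": [len(g.peptides) for g in accepted_groups],
            "protein_score": [g.protein_score for g in accepted_groups],
            "is_decoy": [g.is_decoy for g in accepted_groups],
        }
    )
    write_tsv(group_frame, outdir / "protein_groups.tsv", index=False)

    pep_to_group = {}
    for g in accepted_groups:
        for pep in g.peptides:
            pep_to_group[pep] = g.representative
    peptide_by_scan = {
        p.scan_id: (p.peptide, pep_to_group[p.peptide])
        for p in accepted
        if p.peptide in pep_to_group
    }

    summary: dict = {
        "version": __version__,
        "n_psms": len(psms),
        "n_psms_accepted": len(accepted),
        "n_protein_groups": len(groups),
        "n_protein_groups_accepted": len(accepted_groups),
        "tissues": {},
    }

    diff_sets: dict[str, set] = {}
    for tissue in design.tissues:
        plex_tables = {}
        for plex in design.plexes_for(tissue):
            spectra = all_spectra[plex.plex_id]
            quants = quantify_spectra(spectra, peptide_by_scan, impurity)
            kept = filter_quantifiable(quants, config.min_total_sn, config.min_specificity)
            logger.info("%s: %d/%d quantifiable PSMs", plex.plex_id, len(kept), len(quants))
            write_tsv(
                quantified_to_frame(kept, TMT10_CHANNEL_NAMES),
                outdir / f"{plex.plex_id}.quant.tsv",
                index=False,
            )
            if not kept:
                continue
            mat = pd.DataFrame(
                [q.corrected_sn for q in kept],
                index=pd.Index([q.scan_id for q in kept], name="scan_id"),
                columns=[c.subject for c in plex.channels],
            )
            normalized, _ = normalize_channels(mat)
            assignment = pd.Series({q.scan_id: q.protein for q in kept})
            plex_tables[plex.plex_id] = rollup_proteins(normalized, assignment)
        table = aggregate_plexes(plex_tables, design, tissue, scaling=config.plex_scaling)
        write_quant_table(table, outdir / f"{tissue}.proteins.tsv")

        results = test_table(table, config.min_n, config.equal_var, config.log_scale)
        classified = classify_differential(results, config.alpha, config.up_fc, config.down_fc)
        write_tsv(classified, outdir / f"{tissue}.differential.tsv")
        counts = summarize_calls(classified)
        diff_sets[tissue] = set(classified.index[classified["call"].isin(["up", "down"])])
        summary["tissues"][tissue] = {
            "n_proteins_quantified": int(table.data.shape[0]),
            **counts,
        }
        try:
            qc = qc_surfaces(table, classified)
            write_tsv(qc.volcano, outdir / f"{tissue}.volcano.tsv")
            write_tsv(qc.pca_scores, outdir / f"{tissue}.pca.tsv")
            write_tsv(qc.sample_summaries, outdir / f"{tissue}.sample_summaries.tsv")
        except ValueError as exc:
            logger.warning("%s: QC surfaces skipped (%s)", tissue, exc)

    if len(diff_sets) == 2:
        (t_a, s_a), (t_b, s_b) = diff_sets.items()
        ov = venn_overlap(s_a, s_b)
        summary["overlap"] = {
            f"only_{t_a}": ov.only_a, "shared": ov.shared, f"only_{t_b}": ov.only_b,
        }

    config.to_yaml(outdir / "config.yaml")
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return summary
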