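"""End-to-end orchestration of the integration pipeline.

Stages: simulate (or load) paired data -> normalize (RPMPCG / Q75 +
prevalence filters) -> paired NB differential expression with the FC/FDR
gate -> bootstrap-calibrated association of gated mRNAs with retained
miRNAs -> seed scan of the UTR catalog -> four-way classification and
network export. Used by the command-line interface; each step is also
callable on its own.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import io
from .association import DifferentialAssociation, differentials
from .classify import assemble_interactions, export_network, summarize
from .containers import PairedExpressionSet
from .diffexpr import PairedNBDE, fold_change, stratum_unique
from .normalization import prevalence_filter, q75_scale, rpmpcg_normalize
from .seeds import MatureMiRNA, SeedMatcher
from .synthetic import (
    GroundTruth,
    SimulationConfig,
    simulate_metadata,
    simulate_mirna_catalog,
    simulate_mirna_signals,
    simulate_paired_counts,
    simulate_utrs,
)


def simulate_study(config: SimulationConfig, outdir: Path | None = None, clean_utrs: bool = False):
    """Generate a complete synthetic study; optionally write it to ``outdir``."""
    counts, truth = simulate_paired_counts(config)
    signals = simulate_mirna_signals(config, truth, counts)
    catalog = simulate_mirna_catalog(config, clean_compatible=clean_utrs)
    utrs, truth = simulate_utrs(config, truth, catalog, clean=clean_utrs)
    metadata = simulate_metadata(config)
    study = {
        "counts": counts,
        "signals": signals,
        "catalog": catalog,
        "utrs": utrs,
        "metadata": metadata,
        "truth": truth,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_matrix(counts.values, outdir / "counts.tsv")
        io.write_matrix(signals.values, outdir / "signals.tsv")
        io.write_metadata(metadata, outdir / "metadata.tsv")
        io.write_mirna_fasta(catalog, outdir / "mirnas.fasta")
        io.write_utr_fasta([(u.gene, u.isoform, u.assembly, u.sequence) for u in utrs], outdir / "utrs.fasta")
        io.write_id_list(config.gene_ids, outdir / "protein_coding.txt")
        truth.to_json(outdir / "ground_truth.json")
    return study


def subject_covariates(metadata: pd.DataFrame) -> pd.DataFrame:
    """Age/sex covariate frame indexed by subject (one row per subject)."""
    per_subject = metadata.drop_duplicates("subject_id").set_index("subject_id")
    return per_subject[["age", "sex"]].astype(float)


def run_pipeline(
    counts: PairedExpressionSet,
    signals: PairedExpressionSet,
    metadata: pd.DataFrame,
    utrs,
    catalog: dict[str, str],
    protein_coding_ids=None,
    pathway_genes=None,
    bootstrap_reps: int = 1000,
    seed: int = 0,
    seed_mode: str = "literal",
    de_method: str = "random",
    mrna_min_fraction: float = 0.5,
    mirna_min_fraction: float = 0.20,
    q_threshold: float = 0.05,
) -> dict:
    """Run every stage and return a dict of result tables."""
    pc = list(protein_coding_ids) if protein_coding_ids is not None else list(counts.feature_ids)

    counts_kept = prevalence_filter(counts, mrna_min_fraction, reference="all")
    genes = [g for g in (pathway_genes or counts_kept.feature_ids) if g in set(counts_kept.feature_ids)]

    de = PairedNBDE(genes=genes, method=de_method).fit(counts, protein_coding_ids=pc)
    gated = de.passed_genes_

    signals_norm = q75_scale(signals)
    signals_kept = prevalence_filter(signals_norm, mirna_min_fraction, reference="normal_only")

    rpm = rpmpcg_normalize(counts, pc)
    d_mrna = differentials(rpm).loc[gated] if gated else pd.DataFrame()
    d_mirna = differentials(signals_kept)
    covariates = subject_covariates(metadata)

    assoc_res = pd.DataFrame(columns=["gene", "mirna", "n", "beta_raw", "beta_std", "f_stat", "p_raw", "q", "flag"])
    if len(d_mrna) and len(d_mirna):
        assoc = DifferentialAssociation(bootstrap_reps=bootstrap_reps, seed=seed).fit(
            d_mrna, d_mirna, covariates
        )
        assoc_res = assoc.results_

    matcher = SeedMatcher(mode=seed_mode)
    mirnas = [MatureMiRNA(name, seq) for name, seq in catalog.items()]
    sites = matcher.scan(utrs, mirnas)
    flags = matcher.match_matrix(utrs, mirnas)

    mirna_fc = pd.Series(
        {m: fold_change(signals_kept, m)[2] for m in signals_kept.feature_ids}, dtype=float
    )
    interactions = assemble_interactions(assoc_res, flags, q_threshold=q_threshold, mirna_fc=mirna_fc)
    summary = summarize(interactions[["gene", "mirna", "beta", "seed_match"]]) if len(interactions) else summarize(
        pd.DataFrame(columns=["gene", "mirna", "beta", "seed_match"])
    )
    return {
        "de_table": de.results_,
        "gated_genes": gated,
        "associations": assoc_res,
        "sites": sites,
        "seed_flags": flags,
        "interactions": interactions,
        "summary": summary,
    }


def run_stratified_de(
    counts: PairedExpressionSet,
    metadata: pd.DataFrame,
    protein_coding_ids=None,
    genes=None,
    de_method: str = "random",
):
    """Overall plus MSS/MSI-stratified DE; returns fits and stratum-unique genes."""
    pc = list(protein_coding_ids) if protein_coding_ids is not None else list(counts.feature_ids)
    per_subject = metadata.drop_duplicates("subject_id").set_index("subject_id")
    fits = {"overall": PairedNBDE(genes=genes, method=de_method).fit(counts, pc)}
    for label, mask in (("MSS", per_subject["msi"] == 0), ("MSI", per_subject["msi"] == 1)):
        subjects = per_subject.index[mask]
        if len(subjects) < 3:
            continue
        sub = counts.subset_subjects(subjects)
        fits[label] = PairedNBDE(genes=genes, method=de_method, stratum=label).fit(sub, pc)
    unique = {
        label: stratum_unique(fits["overall"].passed_genes_, fits[label].passed_genes_)
        for label in fits
        if label != "overall"
    }
    return fits, unique


def write_manifest(outdir: Path, command: str, params: dict, outputs: list[str]) -> None:
    from . import __version__

    manifest = {
        "tool": "mirpair",
        "version": __version__,
        "command": command,
        "params": params,
        "outputs": sorted(outputs),
    }
    with open(Path(outdir) / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
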