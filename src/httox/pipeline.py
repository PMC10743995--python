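"""End-to-end orchestration: QC -> normalize -> (optional extrapolation) ->
differential expression -> gene-set scoring -> injury calls -> clustering.

Every output is declared in a run manifest (JSON) together with the stage
parameters and seeds, so a rerun with the same config reproduces the run.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .cluster_corr import cluster, common_genes, condition_correlation, pairwise_significant_counts, to_newick
from .config import PipelineConfig
from .differential import deg_counts, differential_expression, fold_change_matrix
from .extrapolate import ExtrapolationModel, predict
from .geneset_scoring import read_gmt, score_all, write_gmt
from .injury_calls import call_all, summarize_phenotypes
from .io import load_probe_counts, read_sample_sheet, write_counts_tsv, write_manifest, write_sample_sheet
from .qc_normalize import apply_qc, collapse_probes, detect_outliers, normalize, qc_flag, unattenuate

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _synthetic_inputs(cfg: PipelineConfig):
    from . import synth  # deferred: synth imports qc_normalize/geneset types

    design = synth.default_design()
    if cfg.synth_n_chemicals < len(design.chemicals):
        by_class = {"hepatotoxic": [], "non_hepatotoxic": [], "non_toxic": []}
        for c in design.chemicals:
            by_class[design.toxicity_class[c]].append(c)
        n_hep = max(1, cfg.synth_n_chemicals // 2)
        n_non = cfg.synth_n_chemicals - n_hep
        keep = by_class["hepatotoxic"][:n_hep] + (by_class["non_toxic"] + by_class["non_hepatotoxic"])[:n_non]
        design = synth.StudyDesign(
            chemicals=sorted(keep),
            dose_values={c: design.dose_values[c] for c in keep},
            toxicity_class={c: design.toxicity_class[c] for c in keep},
            vehicle={c: design.vehicle[c] for c in keep},
            n_replicates=design.n_replicates,
        )
    genes = [f"g{i:05d}" for i in range(cfg.synth_n_genes)]
    sig = synth.make_signatures(design, genes, seed=cfg.seed)
    counts, sheet = synth.generate_counts(design, sig, genes=genes, seed=cfg.seed,
                                          qc_fail_fraction=0.02)
    sets = synth.generate_genesets(sig, genes, n_decoy_sets=10, seed=cfg.seed)
    return counts, sheet, sets, design


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run all stages under ``cfg`` and return the output directory."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "httox_version": __version__,
        "config": dataclasses.asdict(cfg),
        "outputs": {},
    }

    def emit(key: str, name: str):
        manifest["outputs"][key] = name
        return out / name

    # --- inputs
    if cfg.synthetic:
        counts, sheet, sets, _design = _synthetic_inputs(cfg)
        write_counts_tsv(counts.counts, emit("counts", "counts.tsv"))
        write_manifest(counts.manifest, emit("probe_manifest", "probe_manifest.tsv"))
        write_sample_sheet(sheet, emit("samples", "samples.tsv"))
        if cfg.gene_sets:
            sets = read_gmt(cfg.gene_sets)
        else:
            write_gmt(sets, emit("gene_sets", "gene_sets.gmt"))
    else:
        counts = load_probe_counts(cfg.counts, cfg.manifest)
        sheet = read_sample_sheet(cfg.samples)
        sets = read_gmt(cfg.gene_sets)

    # --- QC + normalization
    report = qc_flag(sheet, counts)
    report.table.to_csv(emit("qc_report", "qc_report.tsv"), sep="\t")
    counts_q, sheet_q = apply_qc(counts, sheet, report, keep_flagged=cfg.keep_flagged)
    norm = normalize(unattenuate(counts_q))
    outliers = detect_outliers(norm, sheet_q, r_min=cfg.r_min)
    report.outliers = outliers
    (out / "qc_summary.json").write_text(json.dumps(
        {"flagged": report.flagged, "outliers": outliers}, indent=2))
    manifest["outputs"]["qc_summary"] = "qc_summary.json"
    if outliers and not cfg.keep_flagged:
        counts_q, sheet_q = apply_qc(counts_q, sheet_q, report, keep_flagged=False)
        norm = normalize(unattenuate(counts_q))
    gene_norm = collapse_probes(norm, counts.manifest, policy=cfg.collapse_policy)
    gene_norm.values.to_csv(emit("normalized", "normalized_log2rpm.tsv"), sep="\t")

    # --- optional extrapolation to the whole transcriptome
    if cfg.model:
        model = ExtrapolationModel.load(cfg.model)
        extrap = predict(model, gene_norm.values, passthrough_sentinel=cfg.passthrough_sentinel)
        extrap.to_csv(emit("extrapolated", "extrapolated_log2rpm.tsv"), sep="\t")
        values = extrap
    else:
        values = gene_norm.values

    # --- differential expression
    profiles = differential_expression(values, sheet_q, scope=cfg.scope)
    fcmat = fold_change_matrix(profiles)
    flat = fcmat.copy()
    flat.columns = [f"{c}|{d}" for c, d in fcmat.columns]
    flat.to_csv(emit("fold_changes", "fold_changes.tsv"), sep="\t")
    degs = deg_counts(profiles, q_threshold=cfg.deg_q_threshold)
    degs.to_csv(emit("deg_counts", "deg_counts.tsv"), sep="\t", index=False)

    # --- gene-set scoring + injury calls
    scores = score_all(profiles, sets, method=cfg.score_method,
                       n_perm=cfg.n_perm, seed=cfg.seed)
    scores.to_csv(emit("scores", "geneset_scores.tsv"), sep="\t", index=False)
    injury_scores = scores[scores["phenotype_group"] != "none"]
    calls = call_all(injury_scores if len(injury_scores) else scores,
                     z_min=cfg.z_min, p_max=cfg.p_max, k_consecutive=cfg.k_consecutive)
    calls_df = pd.DataFrame(
        [
            {
                "chemical": c.chemical,
                "module_id": c.module_id,
                "phenotype_group": c.phenotype_group,
                "status": c.status,
                "supporting_doses": ",".join(map(str, c.supporting_doses)),
            }
            for c in calls
        ]
    )
    calls_df.to_csv(emit("injury_calls", "injury_calls.tsv"), sep="\t", index=False)
    pheno = summarize_phenotypes(calls)
    pheno.to_csv(emit("phenotype_summary", "phenotype_summary.tsv"), sep="\t")
    (out / "phenotype_summary.json").write_text(
        json.dumps({c: {g: bool(v) for g, v in row.items()} for c, row in pheno.iterrows()}, indent=2))
    manifest["outputs"]["phenotype_summary_json"] = "phenotype_summary.json"

    # --- clustering, correlation, consensus
    cols = cluster(fcmat, axis="cols")
    (out / "condition_dendrogram.nwk").write_text(to_newick(cols) + "\n")
    manifest["outputs"]["condition_dendrogram"] = "condition_dendrogram.nwk"
    corr = condition_correlation(fcmat)
    corr.to_csv(emit("condition_correlation", "condition_correlation.tsv"), sep="\t")
    chems = cfg.consensus_chemicals or sorted({p.chemical for p in profiles})
    consensus = common_genes(profiles, chems, q_threshold=cfg.q_threshold)
    (out / "common_genes.txt").write_text("\n".join(consensus.members) + "\n")
    manifest["outputs"]["common_genes"] = "common_genes.txt"
    pairwise_significant_counts(profiles, chems, q_threshold=cfg.q_threshold).to_csv(
        emit("pairwise_significant", "pairwise_significant_counts.tsv"), sep="\t")

    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
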