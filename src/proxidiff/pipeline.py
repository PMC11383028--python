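"""End-to-end orchestration of the differential-proximity pipeline."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io
from .containers import (
    PeptideQuantMatrix,
    PipelineConfig,
    ProteinQuantMatrix,
    SampleDesign,
)
from .interactome import (
    EnrichmentCall,
    InteractorCallSet,
    bait_enrichment,
    call_high_confidence,
    genotype_contrast,
)
from .preprocess import ImputationAudit, preprocess
from .qc import QCSummary, qc_summary
from .rollup import PeptideProteinMap, assign_razor, group_proteins, rollup


@dataclass
class PipelineResult:
    """Everything a run produces, from the processed matrices to the
    high-confidence gained/lost interactor lists."""

    peptides: PeptideQuantMatrix
    audit: ImputationAudit
    factors: dict[str, pd.Series]
    pmap: PeptideProteinMap
    proteins: ProteinQuantMatrix
    enrich_wt: EnrichmentCall
    enrich_gs: EnrichmentCall
    contrast: pd.DataFrame
    calls: InteractorCallSet
    qc: QCSummary


def run_pipeline(
    matrix: PeptideQuantMatrix,
    candidates: dict[str, tuple[str, ...]],
    design: SampleDesign,
    config: PipelineConfig,
    protein_lengths: dict[str, int] | None = None,
) -> PipelineResult:
    """Run filter -> normalize -> impute -> normalize -> roll-up ->
    contrasts -> interactor calls -> QC on an in-memory dataset."""
    peptides, audit, factors = preprocess(matrix, design, config)
    pmap = assign_razor(PeptideProteinMap(candidates), peptides)
    pmap = group_proteins(pmap, protein_lengths=protein_lengths)
    proteins = rollup(peptides, pmap)
    floor = audit.zero_floor
    enrich_wt = bait_enrichment(proteins, design, "WT", config, floor)
    enrich_gs = bait_enrichment(proteins, design, "GS", config, floor)
    contrast = genotype_contrast(proteins, design, config, floor)
    calls = call_high_confidence(enrich_wt, enrich_gs, contrast, config)
    qc = qc_summary(proteins, design, floor)
    return PipelineResult(
        peptides=peptides, audit=audit, factors=factors, pmap=pmap,
        proteins=proteins, enrich_wt=enrich_wt, enrich_gs=enrich_gs,
        contrast=contrast, calls=calls, qc=qc,
    )


def result_tables(result: PipelineResult) -> dict[str, pd.DataFrame]:
    """Flatten a :class:`PipelineResult` into named output tables."""

    def with_accession(table: pd.DataFrame) -> pd.DataFrame:
        out = table.reset_index(names="accession")
        return out

    tables = {
        "enrichment_WT_EZR_vs_CYT": with_accession(result.enrich_wt.table),
        "enrichment_GS_EZR_vs_CYT": with_accession(result.enrich_gs.table),
        "contrast_GS_vs_WT_EZR": with_accession(result.contrast),
        "high_confidence_calls": result.calls.provenance,
        "imputation_audit": result.audit.records,
        "peptide_map_resolved": result.pmap.to_frame(),
        "normalization_factors": pd.DataFrame({
            "sample_id": result.factors["total"].index,
            "total_intensity_factor": result.factors["total"].to_numpy(),
            "trimmed_mean_factor": result.factors["trimmed"].to_numpy(),
        }),
        "qc_summary": pd.DataFrame({
            "metric": (
                ["mean_spqc_pct_cv"]
                + [f"mean_pct_cv_{g}" for g in result.qc.group_mean_cv.index]
                + [f"pca_explained_variance_PC{k + 1}"
                   for k in range(len(result.qc.pca_explained_variance))]
            ),
            "value": (
                [result.qc.spqc_mean_cv]
                + list(result.qc.group_mean_cv.to_numpy())
                + list(result.qc.pca_explained_variance)
            ),
        }),
        "pca_coordinates": result.qc.pca_coordinates.reset_index(
            names="sample_id"
        ),
    }
    return tables


def run_from_files(
    peptides_path: str | Path,
    map_path: str | Path,
    design_path: str | Path,
    config: PipelineConfig,
    out_dir: str | Path,
) -> tuple[PipelineResult, list[str]]:
    """File-level entry point used by the CLI: read inputs, run, write the
    result tables plus run metadata; returns (result, manifest)."""
    matrix = io.read_peptide_table(peptides_path, config.missing_dialect)
    candidates = io.read_peptide_map(map_path)
    design = io.read_design(design_path)
    result = run_pipeline(matrix, candidates, design, config)
    manifest = io.write_results(result_tables(result), out_dir, config)
    return result, manifest
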