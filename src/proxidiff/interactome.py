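"""Two-stage bait-enrichment interactor calling.

Stage 1 identifies proteins enriched near the bait within each genotype
(Ezrin-BioID vs cytosolic-BioID, signed fold-change above the screen
threshold at unadjusted p below threshold). Stage 2 contrasts the two
genotypes' bait pull-downs; proteins that are bait-enriched in the mutant
*and* up in the genotype contrast gained proximity, proteins bait-enriched
in wild type *and* down in the contrast lost proximity. The two lists are
disjoint by construction (opposite-sign contrast requirements).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .containers import PipelineConfig, ProteinQuantMatrix, SampleDesign
from .differential import differential_table
from .errors import ConsistencyError, StatisticsError


@dataclass
class EnrichmentCall:
    """Bait-vs-control enrichment within one genotype: the full
    differential table (EZR vs CYT) and the enriched protein set."""

    genotype: str
    table: pd.DataFrame
    enriched: frozenset[str]


@dataclass
class InteractorCallSet:
    """High-confidence gained/lost proximity calls with provenance.

    ``provenance`` has one row per called protein: which genotype's
    enrichment set admitted it, its bait-enrichment signed FC, and the
    genotype-contrast signed FC and p that confirmed it.
    """

    gained: frozenset[str]
    lost: frozenset[str]
    provenance: pd.DataFrame


def bait_enrichment(
    proteins: ProteinQuantMatrix,
    design: SampleDesign,
    genotype: str,
    config: PipelineConfig,
    zero_floor: float,
) -> EnrichmentCall:
    """EZR vs CYT differential within one genotype; enriched means
    signed_FC > fc_threshold with unadjusted p < p_threshold."""
    ezr = design.samples_for(genotype, "EZR")
    cyt = design.samples_for(genotype, "CYT")
    if len(ezr) < 2 or len(cyt) < 2:
        raise StatisticsError(
            f"genotype {genotype!r} needs >= 2 replicates of both constructs"
        )
    table = differential_table(proteins, ezr, cyt, config, zero_floor)
    enriched = table.index[
        (table["signed_FC"] > config.fc_threshold)
        & (table["p"] < config.p_threshold)
    ]
    return EnrichmentCall(
        genotype=genotype, table=table, enriched=frozenset(map(str, enriched))
    )


def genotype_contrast(
    proteins: ProteinQuantMatrix,
    design: SampleDesign,
    config: PipelineConfig,
    zero_floor: float,
) -> pd.DataFrame:
    """Mutant vs wild-type contrast of the bait pull-downs (GS-EZR vs
    WT-EZR), labeled Up/Down; this is the volcano-plot table."""
    gs = design.samples_for("GS", "EZR")
    wt = design.samples_for("WT", "EZR")
    if len(gs) < 2 or len(wt) < 2:
        raise StatisticsError("both genotypes need >= 2 EZR replicates")
    return differential_table(proteins, gs, wt, config, zero_floor)


def call_high_confidence(
    enrich_wt: EnrichmentCall,
    enrich_gs: EnrichmentCall,
    contrast: pd.DataFrame,
    config: PipelineConfig,
) -> InteractorCallSet:
    """Intersect per-genotype bait enrichment with the genotype contrast.

    gained = GS-enriched proteins whose contrast signed_FC exceeds
    fc_threshold; lost = WT-enriched proteins whose contrast signed_FC is
    below -fc_threshold. When ``config.require_contrast_p`` (default) the
    contrast additionally requires unadjusted p < p_threshold.
    """
    universes = {
        frozenset(map(str, enrich_wt.table.index)),
        frozenset(map(str, enrich_gs.table.index)),
        frozenset(map(str, contrast.index)),
    }
    if len(universes) != 1:
        raise ConsistencyError("enrichment and contrast protein universes differ")

    p_ok = (
        contrast["p"] < config.p_threshold
        if config.require_contrast_p
        else pd.Series(True, index=contrast.index)
    )
    up = set(contrast.index[(contrast["signed_FC"] > config.fc_threshold) & p_ok])
    down = set(contrast.index[(contrast["signed_FC"] < -config.fc_threshold) & p_ok])
    gained = frozenset(enrich_gs.enriched & up)
    lost = frozenset(enrich_wt.enriched & down)

    rows = []
    for acc in sorted(gained | lost):
        call = "gained" if acc in gained else "lost"
        source = enrich_gs if call == "gained" else enrich_wt
        rows.append({
            "accession": acc,
            "call": call,
            "enriched_in": source.genotype,
            "bait_signed_FC": float(source.table.loc[acc, "signed_FC"]),
            "bait_p": float(source.table.loc[acc, "p"]),
            "contrast_signed_FC": float(contrast.loc[acc, "signed_FC"]),
            "contrast_p": float(contrast.loc[acc, "p"]),
        })
    provenance = pd.DataFrame(
        rows,
        columns=["accession", "call", "enriched_in", "bait_signed_FC",
                 "bait_p", "contrast_signed_FC", "contrast_p"],
    )
    return InteractorCallSet(gained=gained, lost=lost, provenance=provenance)
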