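"""Core in-memory containers for the BioID quantification pipeline.

The pipeline moves a peptide x sample intensity matrix through a fixed
sequence of stages (raw -> filtered -> total_normalized -> imputed ->
trimmed_normalized), guided by a sample design that partitions columns
into biological groups (genotype x construct) plus SPQC pool injections.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, StateError

STAGES = ("raw", "filtered", "total_normalized", "imputed", "trimmed_normalized")

GENOTYPES = ("WT", "GS")
CONSTRUCTS = ("EZR", "CYT")

#: Label used for the pooled-QC pseudo-group in imputation and QC.
SPQC_GROUP = "SPQC"


def _stage_index(stage: str) -> int:
    try:
        return STAGES.index(stage)
    except ValueError:
        raise StateError(f"unknown stage {stage!r}; expected one of {STAGES}") from None


@dataclass
class PeptideQuantMatrix:
    """Peptide x sample intensities with an explicit missingness mask.

    ``intensity`` holds finite non-negative values; entries where
    ``observed`` is False are stored as 0.0 but carry no quantitative
    meaning until imputation. ``stage`` records pipeline progress and may
    only advance along :data:`STAGES`.
    """

    intensity: pd.DataFrame
    observed: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        _stage_index(self.stage)
        if not self.intensity.index.equals(self.observed.index) or not (
            self.intensity.columns.equals(self.observed.columns)
        ):
            raise FormatError("intensity and observed mask must share index/columns")
        if self.intensity.index.has_duplicates:
            raise FormatError("duplicate peptide ids")
        if self.intensity.columns.has_duplicates:
            raise FormatError("duplicate sample ids")
        vals = self.intensity.to_numpy(dtype=float)
        obs = self.observed.to_numpy(dtype=bool)
        if not np.all(np.isfinite(vals[obs])):
            raise FormatError("observed intensities must be finite")
        if np.any(vals[obs] < 0):
            raise FormatError("negative intensity")
        if _stage_index(self.stage) >= _stage_index("imputed") and not obs.all():
            raise StateError(f"stage {self.stage!r} requires a fully observed matrix")

    # -- convenience ---------------------------------------------------

    @property
    def peptide_ids(self) -> pd.Index:
        return self.intensity.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensity.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape

    def copy(self) -> "PeptideQuantMatrix":
        return PeptideQuantMatrix(
            self.intensity.copy(), self.observed.copy(), self.stage
        )

    def advanced(
        self, intensity: pd.DataFrame, observed: pd.DataFrame, stage: str
    ) -> "PeptideQuantMatrix":
        """Return a new matrix at a later stage, enforcing stage order."""
        if _stage_index(stage) <= _stage_index(self.stage):
            raise StateError(f"cannot move from {self.stage!r} to {stage!r}")
        return PeptideQuantMatrix(intensity, observed, stage)


class SampleDesign:
    """Per-sample annotations: genotype, construct, replicate, SPQC flag.

    Biological groups are the genotype x construct cells of the design;
    SPQC pool injections are excluded from every biological group and are
    handled as their own technical-replicate set.
    """

    REQUIRED = ("sample_id", "genotype", "construct", "replicate", "is_spqc")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise FormatError(f"design is missing columns {missing}")
        if len(table) == 0:
            raise FormatError("empty design")
        table = table.reset_index(drop=True).copy()
        table["is_spqc"] = table["is_spqc"].astype(bool)
        if table["sample_id"].duplicated().any():
            raise FormatError("duplicate sample ids in design")
        bio = table[~table["is_spqc"]]
        bad_geno = set(bio["genotype"]) - set(GENOTYPES)
        if bad_geno:
            raise FormatError(f"unknown genotype token(s) {sorted(bad_geno)}")
        bad_con = set(bio["construct"]) - set(CONSTRUCTS)
        if bad_con:
            raise FormatError(f"unknown construct token(s) {sorted(bad_con)}")
        if bio[["genotype", "construct", "replicate"]].duplicated().any():
            raise FormatError("duplicated (genotype, construct, replicate)")
        if (bio["replicate"].astype(int) < 1).any():
            raise FormatError("replicate indices must be positive")
        self.table = table

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SampleDesign) and self.table.equals(other.table)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def spqc_samples(self) -> list[str]:
        return list(self.table.loc[self.table["is_spqc"], "sample_id"])

    def biological_groups(self) -> dict[str, list[str]]:
        """Map ``"<genotype>_<construct>"`` to its ordered sample ids."""
        bio = self.table[~self.table["is_spqc"]]
        groups: dict[str, list[str]] = {}
        for _, row in bio.iterrows():
            groups.setdefault(f"{row['genotype']}_{row['construct']}", []).append(
                row["sample_id"]
            )
        return groups

    def imputation_groups(self) -> dict[str, list[str]]:
        """Biological groups plus the SPQC pool as its own group."""
        groups = self.biological_groups()
        spqc = self.spqc_samples
        if spqc:
            groups[SPQC_GROUP] = spqc
        return groups

    def samples_for(self, genotype: str, construct: str) -> list[str]:
        bio = self.table[~self.table["is_spqc"]]
        sel = bio[(bio["genotype"] == genotype) & (bio["construct"] == construct)]
        return list(sel["sample_id"])

    def small_groups(self) -> list[str]:
        """Biological groups with fewer than 2 replicates (flagged at read
        time; downstream statistics refuse them)."""
        return [g for g, s in self.biological_groups().items() if len(s) < 2]


@dataclass
class PipelineConfig:
    """Tunable constants of the quantification pipeline.

    Defaults are the study's printed values: fold-change screen at 1.5,
    unadjusted p at 0.05, 10% trimming per tail, 20 intensity bins for
    imputation, misalignment cutoff 5e6, low-value floor at the 2nd
    percentile of detected intensities.
    """

    missing_dialect: str = "blank_is_missing"
    fc_threshold: float = 1.5
    p_threshold: float = 0.05
    trim_fraction: float = 0.10
    n_bins: int = 20
    misaligned_cutoff: float = 5e6
    low_percentile: float = 0.02
    seed: int | None = None
    #: whether the genotype-contrast requirement of the high-confidence
    #: interactor call also demands p < p_threshold (default on).
    require_contrast_p: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.trim_fraction < 0.5):
            raise ParameterError("trim_fraction must lie in (0, 0.5)")
        if not (0 < self.low_percentile < 1):
            raise ParameterError("low_percentile must lie in (0, 1)")
        if not self.fc_threshold > 1:
            raise ParameterError("fc_threshold must exceed 1")
        if not (0 <= self.p_threshold <= 1):
            raise ParameterError("p_threshold must be a probability")
        if self.n_bins < 1:
            raise ParameterError("n_bins must be positive")
        if self.misaligned_cutoff <= 0:
            raise ParameterError("misaligned_cutoff must be positive")
        if self.missing_dialect not in ("blank_is_missing", "zero_is_missing"):
            raise ParameterError(f"unknown missing dialect {self.missing_dialect!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ProteinQuantMatrix:
    """Protein (group master) x sample intensities after peptide roll-up."""

    intensity: pd.DataFrame
    peptide_counts: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))

    def __post_init__(self) -> None:
        if self.intensity.index.has_duplicates:
            raise FormatError("duplicate protein accessions")
        if np.any(self.intensity.to_numpy(dtype=float) < 0):
            raise FormatError("negative protein intensity")
        if len(self.peptide_counts) and (self.peptide_counts < 1).any():
            raise FormatError("protein with zero peptides")

    @property
    def protein_ids(self) -> pd.Index:
        return self.intensity.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensity.columns
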