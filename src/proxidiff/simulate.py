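"""Synthetic BioID datasets with known ground truth.

The generator emulates the statistical structure of an in-vivo proximity
labeling experiment contrasting a membrane-cytoskeleton bait (Ezrin-BioID,
"EZR") against a soluble cytosolic control ("CYT") in two genotypes (WT
and a kinase-hyperactive mutant, "GS"), 3 biological replicates each, plus
3 injections of a pooled study-wide QC sample (SPQC):

* protein base abundances and peptide ionizabilities are log-normal;
* bait-proximal proteins are enriched by ``bait_enrichment_fold`` in every
  EZR column;
* a subset of bait-proximal proteins gains or loses proximity in the
  mutant: their GS-EZR abundance is multiplied or divided by
  ``genotype_fold``;
* biological and technical noise both act at the protein level (shared
  by a protein's peptides within an injection), so protein-level %CVs
  after roll-up reflect the generating CVs directly;
* SPQC columns are the noiseless pool mean of the 12 biological columns
  plus technical noise only, so their %CV estimates technical precision;
* missingness is left-censoring-like (logistic dropout in log10
  intensity) plus rare "misaligned" features: a spurious high intensity in
  one column of one group while the rest of that group goes missing,
  mimicking a cross-run feature-alignment error.

Every output is a deterministic function of the parameter set, including
its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import PeptideQuantMatrix, SampleDesign
from .errors import ParameterError, StateError

#: Log10 spurious-intensity distribution for misaligned features; well
#: above the 5e6 misalignment cutoff so the planted artifact is the one
#: the imputation rule targets.
_MISALIGNED_LOG10_MEAN = 7.5
_MISALIGNED_LOG10_SD = 0.25


@dataclass
class SynthParams:
    """Parameters of the synthetic experiment.

    Defaults mirror the study scale: ~4000 proteins / ~30000 peptides in
    the real data (≈7.5 peptides per protein), ~8% of proteins
    bait-enriched, technical CV ≈ 11% and biological+technical CV ≈ 20%.
    ``n_proteins`` defaults to 2000 to keep simulated datasets quick while
    preserving those ratios.
    """

    n_proteins: int = 2000
    peptides_per_protein: tuple[int, int] = (3, 12)
    frac_bait_proximal: float = 0.08
    bait_enrichment_fold: float = 4.0
    frac_genotype_modulated: float = 0.15
    genotype_fold: float = 3.0
    cv_biological: float = 0.165
    cv_technical: float = 0.11
    dropout_midpoint: float = 1e6
    dropout_steepness: float = 3.0
    misaligned_rate: float = 0.01
    shared_peptide_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_bait_proximal", "frac_genotype_modulated",
                     "misaligned_rate", "shared_peptide_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        # fold = 1 is the explicit null condition (no effect).
        if self.bait_enrichment_fold < 1 or self.genotype_fold < 1:
            raise ParameterError("folds must be >= 1")
        if self.n_proteins < 1:
            raise ParameterError("n_proteins must be positive")
        lo, hi = self.peptides_per_protein
        if lo < 1 or hi < lo:
            raise ParameterError("peptides_per_protein must be a valid range")
        if self.cv_biological < 0 or self.cv_technical < 0:
            raise ParameterError("CVs must be non-negative")
        if self.dropout_midpoint <= 0 or self.dropout_steepness <= 0:
            raise ParameterError("dropout parameters must be positive")


@dataclass
class SynthTruth:
    """Ground truth of a simulated dataset.

    ``proteins`` has one row per accession with ``bait_proximal``,
    ``gained``, ``lost`` flags and the expected EZR/CYT abundance ratio in
    each genotype. ``missing_cause`` (peptide x sample, filled by
    :func:`apply_missingness`) records why an entry is missing.
    """

    proteins: pd.DataFrame
    missing_cause: pd.DataFrame | None = field(default=None)

    @property
    def gained(self) -> set[str]:
        return set(self.proteins.index[self.proteins["gained"]])

    @property
    def lost(self) -> set[str]:
        return set(self.proteins.index[self.proteins["lost"]])


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return np.exp(rng.normal(-sigma2 / 2, np.sqrt(sigma2), size=size))


def make_design(n_replicates: int = 3, n_spqc: int = 3) -> SampleDesign:
    """The 12-sample two-genotype x two-construct design plus SPQC pools."""
    rows = []
    for genotype in ("WT", "GS"):
        for construct in ("CYT", "EZR"):
            for rep in range(1, n_replicates + 1):
                rows.append({
                    "sample_id": f"{genotype}_{construct}_{rep}",
                    "genotype": genotype, "construct": construct,
                    "replicate": rep, "is_spqc": False,
                })
    for rep in range(1, n_spqc + 1):
        rows.append({
            "sample_id": f"SPQC_{rep}", "genotype": "", "construct": "",
            "replicate": rep, "is_spqc": True,
        })
    return SampleDesign(pd.DataFrame(rows))


def generate_dataset(
    params: SynthParams,
) -> tuple[PeptideQuantMatrix, dict[str, tuple[str, ...]], SampleDesign, SynthTruth]:
    """Generate a fully observed stage-``raw`` dataset plus ground truth.

    Returns (matrix, peptide->candidates map, design, truth). Apply
    :func:`apply_missingness` afterwards to introduce dropout and
    misaligned features.
    """
    rng = np.random.default_rng([params.seed, 0])
    design = make_design()
    bio = design.table[~design.table["is_spqc"]]
    bio_ids = list(bio["sample_id"])
    spqc_ids = design.spqc_samples

    n_prot = params.n_proteins
    accessions = np.array([f"PRX{i:05d}" for i in range(n_prot)])
    base = 10.0 ** rng.normal(6.5, 0.5, n_prot)

    bait = rng.random(n_prot) < params.frac_bait_proximal
    modulated = bait & (rng.random(n_prot) < params.frac_genotype_modulated)
    direction = rng.random(n_prot) < 0.5
    gained = modulated & direction
    lost = modulated & ~direction

    # Expected per-sample protein abundance (no noise).
    is_ezr = bio["construct"].to_numpy() == "EZR"
    is_gs = bio["genotype"].to_numpy() == "GS"
    fold = np.ones((n_prot, len(bio_ids)))
    fold[bait[:, None] & is_ezr[None, :]] = params.bait_enrichment_fold
    gs_ezr = is_ezr & is_gs
    fold[np.ix_(gained, gs_ezr)] *= params.genotype_fold
    fold[np.ix_(lost, gs_ezr)] /= params.genotype_fold
    prot_mean_bio = base[:, None] * fold
    prot_mean_spqc = prot_mean_bio.mean(axis=1)

    # Biological noise at the protein level, shared by the protein's peptides.
    bio_noise = _lognormal_factor(rng, params.cv_biological, (n_prot, len(bio_ids)))
    # Technical noise likewise at the (protein, injection) level: the
    # peptides of a protein move together within a run, so the %CV of the
    # rolled-up protein reflects the generating technical CV.
    n_cols = len(bio_ids) + len(spqc_ids)
    tech_noise = _lognormal_factor(rng, params.cv_technical, (n_prot, n_cols))

    prot_level = np.concatenate(
        [prot_mean_bio * bio_noise,
         np.repeat(prot_mean_spqc[:, None], len(spqc_ids), axis=1)],
        axis=1,
    ) * tech_noise

    n_pep_per_prot = rng.integers(
        params.peptides_per_protein[0], params.peptides_per_protein[1] + 1, n_prot
    )
    prot_idx = np.repeat(np.arange(n_prot), n_pep_per_prot)
    n_pep = len(prot_idx)
    peptide_ids = np.array([f"PEP{j:06d}" for j in range(n_pep)])
    ionizability = np.exp(rng.normal(0.0, 0.8, n_pep))

    # A fraction of peptides are shared (razor) peptides: the same sequence
    # occurs in a second protein, so the measured ion current is the *sum*
    # of both proteins' contributions.
    shared = (rng.random(n_pep) < params.shared_peptide_rate) & (n_prot > 1)
    other = rng.integers(0, max(n_prot - 1, 1), n_pep)
    other[other >= prot_idx] += 1  # a second protein distinct from the host
    other = np.minimum(other, n_prot - 1)

    full = prot_level[prot_idx]
    full = full + np.where(shared[:, None], prot_level[other], 0.0)
    full = full * ionizability[:, None]

    columns = bio_ids + spqc_ids
    intensity = pd.DataFrame(full, index=peptide_ids, columns=columns)
    intensity.index.name = "peptide_id"
    observed = pd.DataFrame(True, index=intensity.index, columns=columns)
    matrix = PeptideQuantMatrix(intensity, observed, stage="raw")

    candidates: dict[str, tuple[str, ...]] = {}
    for j in range(n_pep):
        accs = [accessions[prot_idx[j]]]
        if shared[j]:
            accs.append(accessions[other[j]])
        candidates[peptide_ids[j]] = tuple(sorted(set(accs)))

    truth_df = pd.DataFrame(
        {
            "bait_proximal": bait,
            "gained": gained,
            "lost": lost,
            "ezr_cyt_ratio_wt": np.where(bait, params.bait_enrichment_fold, 1.0),
            "ezr_cyt_ratio_gs": np.where(bait, params.bait_enrichment_fold, 1.0)
            * np.where(gained, params.genotype_fold, 1.0)
            / np.where(lost, params.genotype_fold, 1.0),
        },
        index=pd.Index(accessions, name="accession"),
    )
    return matrix, candidates, design, SynthTruth(proteins=truth_df)


def apply_missingness(
    matrix: PeptideQuantMatrix, params: SynthParams, design: SampleDesign
) -> tuple[PeptideQuantMatrix, pd.DataFrame]:
    """Censor a fully observed raw matrix with dropout and misalignment.

    Dropout: each entry goes missing with probability
    ``logistic(-steepness * (log10 I - log10 midpoint))`` — low-intensity
    entries are preferentially lost (MNAR). Misalignment: with probability
    ``misaligned_rate`` a peptide that has a biological group with more
    than half its entries dropped out receives a spurious high intensity
    in one of that group's dropped columns — the cross-run aligner
    "finding" a feature that was never genuinely detected there. Returns
    the censored matrix and a per-entry cause table: ``dropout`` marks
    missing entries, ``misaligned`` marks the spurious observed entries,
    everything else is ``observed``.
    """
    if matrix.stage != "raw":
        raise StateError("missingness can only be applied to a raw matrix")
    if not matrix.observed.to_numpy().all():
        raise StateError("missingness already applied")
    rng = np.random.default_rng([params.seed, 1])
    vals = matrix.intensity.to_numpy(dtype=float).copy()
    with np.errstate(divide="ignore"):
        logit = params.dropout_steepness * (
            np.log10(np.maximum(vals, 1e-300)) - np.log10(params.dropout_midpoint)
        )
    p_drop = 1.0 / (1.0 + np.exp(np.clip(logit, -500, 500)))
    dropped = rng.random(vals.shape) < p_drop

    cause = np.full(vals.shape, "observed", dtype=object)
    cause[dropped] = "dropout"

    groups = list(design.biological_groups().items())
    col_pos = {s: i for i, s in enumerate(matrix.sample_ids)}
    group_cols = [np.array([col_pos[s] for s in gs]) for _, gs in groups]
    misaligned_pick = rng.random(vals.shape[0]) < params.misaligned_rate
    for i in np.flatnonzero(misaligned_pick):
        # Misalignment needs runs where the feature was never genuinely
        # detected: model it in groups whose columns all dropped out.
        eligible = [c for c in group_cols if dropped[i, c].all()]
        if not eligible:
            continue
        cols = eligible[rng.integers(len(eligible))]
        dropped_cols = cols[dropped[i, cols]]
        hit = dropped_cols[rng.integers(len(dropped_cols))]
        spurious = 10.0 ** rng.normal(_MISALIGNED_LOG10_MEAN, _MISALIGNED_LOG10_SD)
        vals[i, hit] = spurious
        dropped[i, hit] = False
        cause[i, hit] = "misaligned"

    vals[dropped] = 0.0
    observed = pd.DataFrame(~dropped, index=matrix.peptide_ids,
                            columns=matrix.sample_ids)
    out = PeptideQuantMatrix(
        pd.DataFrame(vals, index=matrix.peptide_ids, columns=matrix.sample_ids),
        observed,
        stage="raw",
    )
    cause_df = pd.DataFrame(cause, index=matrix.peptide_ids,
                            columns=matrix.sample_ids)
    return out, cause_df


def simulate_dataset(
    params: SynthParams,
) -> tuple[PeptideQuantMatrix, dict[str, tuple[str, ...]], SampleDesign, SynthTruth]:
    """Generate a dataset and apply its missingness model in one step."""
    matrix, candidates, design, truth = generate_dataset(params)
    matrix, cause = apply_missingness(matrix, params, design)
    return matrix, candidates, design, replace(truth, missing_cause=cause)
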