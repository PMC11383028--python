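"""Peptide-level preprocessing: filter, normalize, impute, normalize again.

The fixed stage order is

    raw -> filter_peptides -> total_intensity_normalize -> impute
        -> trimmed_mean_normalize

Filtering removes peptides quantified fewer than twice across all runs or
never in at least half the replicates of any single biological group.
Total-intensity normalization equalizes the per-sample observed sums.
Imputation resolves every remaining missing value by one of three
branches (see :func:`impute`). Trimmed-mean normalization then equalizes
per-sample 10%-trimmed means, compensating for scale shifts introduced by
imputation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    SPQC_GROUP,
    PeptideQuantMatrix,
    PipelineConfig,
    SampleDesign,
)
from .errors import (
    ConsistencyError,
    DegenerateInputError,
    ReproducibilityError,
    StateError,
)

logger = logging.getLogger(__name__)

BRANCH_NONE = "none"
BRANCH_BINNED = "binned_normal"
BRANCH_MISALIGNED = "misaligned_zero"
BRANCH_LOW = "low_value"


@dataclass
class ImputationAudit:
    """Provenance of every imputed (peptide, group) cell group.

    ``records`` has one row per (peptide, biological group) that contained
    at least one missing value, with the branch taken, the log10-intensity
    bin used (branch 1 only) and the number of entries filled or zeroed.
    ``low_value_floor`` is the global low-percentile intensity used by
    branch 3; ``zero_floor`` (half of it) is the positive stand-in for
    branch-2 zeros whenever a log2 transform is required downstream.
    """

    records: pd.DataFrame
    low_value_floor: float
    zero_floor: float
    bin_edges: np.ndarray
    fallback_bins: list[int] = field(default_factory=list)

    def branch_for(self, peptide_id: str, group: str) -> str:
        sel = self.records[
            (self.records["peptide_id"] == peptide_id)
            & (self.records["group"] == group)
        ]
        return BRANCH_NONE if sel.empty else str(sel["branch"].iloc[0])


def _check_design(matrix: PeptideQuantMatrix, design: SampleDesign) -> None:
    if set(matrix.sample_ids) != set(design.sample_ids):
        raise ConsistencyError("design samples do not match matrix columns")


def filter_peptides(
    matrix: PeptideQuantMatrix, design: SampleDesign
) -> PeptideQuantMatrix:
    """Keep peptides measured >= 2 times across all runs *and* in >= 50%
    of the replicates of at least one biological group.

    SPQC injections count toward the overall >= 2 rule but do not form a
    biological group for the 50% rule. Idempotent; preserves row order.
    """
    if matrix.stage not in ("raw", "filtered"):
        raise StateError(f"filter expects a raw matrix, got {matrix.stage!r}")
    _check_design(matrix, design)
    obs = matrix.observed
    total_ok = obs.sum(axis=1) >= 2
    group_ok = pd.Series(False, index=matrix.peptide_ids)
    for samples in design.biological_groups().values():
        group_ok |= obs[samples].mean(axis=1) >= 0.5
    keep = total_ok & group_ok
    return PeptideQuantMatrix(
        matrix.intensity.loc[keep].copy(), obs.loc[keep].copy(), stage="filtered"
    )


def total_intensity_normalize(
    matrix: PeptideQuantMatrix,
) -> tuple[PeptideQuantMatrix, pd.Series]:
    """Scale each sample so observed totals all equal their across-sample
    mean. Returns the normalized matrix and the per-sample scale factors."""
    if matrix.stage != "filtered":
        raise StateError(f"expected a filtered matrix, got {matrix.stage!r}")
    vals = matrix.intensity.where(matrix.observed, 0.0)
    totals = vals.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise DegenerateInputError(f"sample(s) with zero observed total: {bad}")
    reference = totals.mean()
    factors = reference / totals
    out = matrix.intensity.mul(factors, axis=1).where(matrix.observed, 0.0)
    return (
        matrix.advanced(out, matrix.observed.copy(), "total_normalized"),
        factors.rename("scale_factor"),
    )


def _truncated_normal(
    rng: np.random.Generator, loc: np.ndarray, scale: np.ndarray
) -> np.ndarray:
    """Draw positive normals by rejection; loc is always > 0 here, so the
    acceptance probability is bounded away from 0."""
    draws = rng.normal(loc, scale)
    for _ in range(100):
        bad = draws <= 0
        if not bad.any():
            break
        draws[bad] = rng.normal(loc[bad], scale[bad])
    else:  # pathological scale >> loc; fall back to the (positive) center
        draws[draws <= 0] = loc[draws <= 0]
    return draws


def impute(
    matrix: PeptideQuantMatrix,
    design: SampleDesign,
    config: PipelineConfig,
) -> tuple[PeptideQuantMatrix, ImputationAudit]:
    """Resolve all missing values with the three-branch strategy.

    Per (peptide, biological group) with missing entries:

    1. *binned_normal* — fewer than half the group missing: each missing
       entry is drawn from a normal distribution fitted to all observed
       values falling in the same intensity bin as the peptide-group's
       observed mean (``n_bins`` equal-width bins over the log10 range of
       all observed values); draws are truncated positive.
    2. *misaligned_zero* — at least half missing and the observed mean
       exceeds ``misaligned_cutoff``: the feature is treated as a
       cross-run alignment artifact and the *entire* peptide-group
       (observed entries included) is set to 0.
    3. *low_value* — everything else (including fully missing groups):
       missing entries are set to the global ``low_percentile`` quantile
       of all observed values.

    SPQC pool columns form their own group and only ever receive branch 3:
    they are technical replicates of a fixed pool, so the biological-group
    branches do not apply. Observed values outside branch 2 are never
    altered. Deterministic given ``config.seed``.
    """
    if matrix.stage != "total_normalized":
        raise StateError(f"expected a total_normalized matrix, got {matrix.stage!r}")
    if config.seed is None:
        raise ReproducibilityError("imputation requires config.seed to be set")
    _check_design(matrix, design)
    rng = np.random.default_rng(config.seed)

    vals = matrix.intensity.to_numpy(dtype=float).copy()
    obs = matrix.observed.to_numpy(dtype=bool)
    observed_vals = vals[obs]
    if observed_vals.size == 0:
        raise DegenerateInputError("matrix has no observed values")
    low_floor = float(np.quantile(observed_vals, config.low_percentile))

    log_obs = np.log10(observed_vals[observed_vals > 0])
    lo, hi = float(log_obs.min()), float(log_obs.max())
    if hi <= lo:  # all observed values identical
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, config.n_bins + 1)
    global_mean = float(observed_vals.mean())
    global_sd = float(observed_vals.std(ddof=1)) if observed_vals.size > 1 else 0.0

    # Per-bin normal fit on the linear intensities of the bin's members.
    pos = observed_vals[observed_vals > 0]
    bin_idx = np.clip(np.digitize(np.log10(pos), edges) - 1, 0, config.n_bins - 1)
    bin_mean = np.full(config.n_bins, global_mean)
    bin_sd = np.full(config.n_bins, global_sd)
    fallback_bins: list[int] = []
    for b in range(config.n_bins):
        members = pos[bin_idx == b]
        if members.size >= 2:
            bin_mean[b] = members.mean()
            bin_sd[b] = members.std(ddof=1)
        else:
            fallback_bins.append(b)
    if fallback_bins:
        logger.info(
            "imputation: %d/%d bins had < 2 observed values; using global "
            "mean/sd for them", len(fallback_bins), config.n_bins,
        )

    col_pos = {s: i for i, s in enumerate(matrix.sample_ids)}
    records: list[dict] = []
    for gname, gsamples in design.imputation_groups().items():
        cols = np.array([col_pos[s] for s in gsamples])
        gobs = obs[:, cols]
        n_missing = (~gobs).sum(axis=1)
        rows = np.flatnonzero(n_missing > 0)
        if rows.size == 0:
            continue
        k = len(cols)
        with np.errstate(invalid="ignore"):
            gmean = np.where(
                n_missing < k,
                (vals[:, cols] * gobs).sum(axis=1) / np.maximum(k - n_missing, 1),
                np.nan,
            )
        frac = n_missing / k
        for i in rows:
            missing_cols = cols[~gobs[i]]
            if gname != SPQC_GROUP and frac[i] < 0.5:
                b = int(np.clip(np.digitize(np.log10(max(gmean[i], 1e-300)),
                                            edges) - 1, 0, config.n_bins - 1))
                draws = _truncated_normal(
                    rng,
                    np.full(missing_cols.size, bin_mean[b]),
                    np.full(missing_cols.size, max(bin_sd[b], 0.0)),
                )
                vals[i, missing_cols] = draws
                records.append({
                    "peptide_id": matrix.peptide_ids[i], "group": gname,
                    "branch": BRANCH_BINNED, "bin": b,
                    "n_imputed": int(missing_cols.size), "floor": np.nan,
                })
            elif (
                gname != SPQC_GROUP
                and not np.isnan(gmean[i])
                and gmean[i] > config.misaligned_cutoff
            ):
                vals[i, cols] = 0.0
                records.append({
                    "peptide_id": matrix.peptide_ids[i], "group": gname,
                    "branch": BRANCH_MISALIGNED, "bin": -1,
                    "n_imputed": int(k), "floor": np.nan,
                })
            else:
                vals[i, missing_cols] = low_floor
                records.append({
                    "peptide_id": matrix.peptide_ids[i], "group": gname,
                    "branch": BRANCH_LOW, "bin": -1,
                    "n_imputed": int(missing_cols.size), "floor": low_floor,
                })

    audit = ImputationAudit(
        records=pd.DataFrame(
            records,
            columns=["peptide_id", "group", "branch", "bin", "n_imputed", "floor"],
        ),
        low_value_floor=low_floor,
        zero_floor=low_floor / 2.0,
        bin_edges=edges,
        fallback_bins=fallback_bins,
    )
    out_vals = pd.DataFrame(vals, index=matrix.peptide_ids, columns=matrix.sample_ids)
    all_true = pd.DataFrame(True, index=matrix.peptide_ids, columns=matrix.sample_ids)
    return matrix.advanced(out_vals, all_true, "imputed"), audit


def trimmed_mean_normalize(
    matrix: PeptideQuantMatrix, config: PipelineConfig
) -> tuple[PeptideQuantMatrix, pd.Series]:
    """Equalize per-sample trimmed means of the positive intensities.

    Per sample, the top and bottom ``trim_fraction`` of the positive
    values (``floor(fraction * n)`` per tail, by rank) are discarded and
    the mean of the remainder taken; every sample is then rescaled so all
    trimmed means equal their across-sample mean. Zeros (misaligned
    features) are excluded from the trimming statistics but are scaled
    like every other value (they stay 0).
    """
    if matrix.stage != "imputed":
        raise StateError(f"expected an imputed matrix, got {matrix.stage!r}")
    vals = matrix.intensity.to_numpy(dtype=float)
    tms = np.empty(vals.shape[1])
    for j in range(vals.shape[1]):
        pos = np.sort(vals[:, j][vals[:, j] > 0])
        if pos.size < 3:
            raise DegenerateInputError(
                f"sample {matrix.sample_ids[j]!r} has < 3 positive values"
            )
        cut = int(np.floor(config.trim_fraction * pos.size))
        trimmed = pos[cut: pos.size - cut] if cut > 0 else pos
        tms[j] = trimmed.mean()
    target = tms.mean()
    factors = pd.Series(target / tms, index=matrix.sample_ids, name="scale_factor")
    out = matrix.intensity.mul(factors, axis=1)
    return (
        matrix.advanced(out, matrix.observed.copy(), "trimmed_normalized"),
        factors,
    )


def preprocess(
    matrix: PeptideQuantMatrix,
    design: SampleDesign,
    config: PipelineConfig,
) -> tuple[PeptideQuantMatrix, ImputationAudit, dict[str, pd.Series]]:
    """Run the full peptide-level chain; returns the final matrix, the
    imputation audit, and both sets of normalization factors."""
    filtered = filter_peptides(matrix, design)
    total_norm, total_factors = total_intensity_normalize(filtered)
    imputed, audit = impute(total_norm, design, config)
    final, trim_factors = trimmed_mean_normalize(imputed, config)
    return final, audit, {"total": total_factors, "trimmed": trim_factors}
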