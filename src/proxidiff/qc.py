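"""Quality-control summaries: per-protein %CV and PCA sample clustering.

%CV over the SPQC pool injections estimates pure technical variability;
%CV within each biological group adds the biological component. The PCA
embedding (log2, per-protein centered) is the standard visual check that
samples cluster by construct (bait vs cytosolic control) before any
differential claim is made.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .containers import ProteinQuantMatrix, SampleDesign
from .errors import StatisticsError

logger = logging.getLogger(__name__)


@dataclass
class QCSummary:
    spqc_cv: pd.Series
    spqc_mean_cv: float
    group_cv: pd.DataFrame
    group_mean_cv: pd.Series
    pca_coordinates: pd.DataFrame
    pca_explained_variance: np.ndarray


def protein_cv(
    proteins: ProteinQuantMatrix, sample_ids: list[str]
) -> tuple[pd.Series, float]:
    """Per-protein %CV (100 * sd / mean, sample sd with n-1 denominator)
    over the named samples, and the mean over proteins.

    Proteins with any non-positive intensity in the sample set are
    excluded (logged) — a zeroed misaligned feature has no meaningful CV.
    """
    if len(sample_ids) < 2:
        raise StatisticsError("%CV needs >= 2 samples")
    missing = [s for s in sample_ids if s not in proteins.sample_ids]
    if missing:
        raise StatisticsError(f"unknown sample(s): {missing}")
    vals = proteins.intensity[sample_ids]
    ok = (vals > 0).all(axis=1)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("%%CV: excluded %d protein(s) with non-positive values",
                    n_excluded)
    sub = vals.loc[ok]
    cv = 100.0 * sub.std(axis=1, ddof=1) / sub.mean(axis=1)
    return cv.rename("pct_cv"), float(cv.mean())


def pca_embed(
    proteins: ProteinQuantMatrix, zero_floor: float
) -> tuple[pd.DataFrame, np.ndarray]:
    """Project samples onto the top-2 PCs of log2, per-protein-centered
    intensities.

    Sign convention: each component is flipped so its largest-magnitude
    protein loading is positive, making the embedding deterministic and
    invariant to sample order (up to that convention).
    """
    n_samples = proteins.intensity.shape[1]
    if n_samples < 3:
        raise StatisticsError("PCA needs >= 3 samples")
    logx = np.log2(np.maximum(proteins.intensity.to_numpy(dtype=float), zero_floor))
    centered = logx - logx.mean(axis=1, keepdims=True)
    X = centered.T  # samples x proteins
    n_comp = min(2, n_samples - 1)
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(X)
    for k in range(n_comp):
        i = int(np.argmax(np.abs(pca.components_[k])))
        if pca.components_[k, i] < 0:
            coords[:, k] *= -1
    cols = [f"PC{k + 1}" for k in range(n_comp)]
    return (
        pd.DataFrame(coords, index=proteins.sample_ids, columns=cols),
        pca.explained_variance_ratio_.copy(),
    )


def qc_summary(
    proteins: ProteinQuantMatrix, design: SampleDesign, zero_floor: float
) -> QCSummary:
    """Compute the full QC bundle: SPQC %CV, per-group %CV, PCA."""
    spqc = design.spqc_samples
    if len(spqc) >= 2:
        spqc_cv, spqc_mean = protein_cv(proteins, spqc)
    else:
        spqc_cv, spqc_mean = pd.Series(dtype=float, name="pct_cv"), float("nan")
    group_cv = {}
    group_mean = {}
    for gname, samples in design.biological_groups().items():
        if len(samples) >= 2:
            cv, mean = protein_cv(proteins, samples)
            group_cv[gname] = cv
            group_mean[gname] = mean
    coords, evr = pca_embed(proteins, zero_floor)
    return QCSummary(
        spqc_cv=spqc_cv,
        spqc_mean_cv=spqc_mean,
        group_cv=pd.DataFrame(group_cv),
        group_mean_cv=pd.Series(group_mean, name="mean_pct_cv"),
        pca_coordinates=coords,
        pca_explained_variance=evr,
    )
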