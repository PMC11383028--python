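"""Per-protein differential statistics between two sample groups.

Fold-changes are computed as differences of group means of log2
intensities; significance by Welch's (heteroscedastic) two-tailed t-test
on the same log2 values; multiplicity by Benjamini-Hochberg. The signed
fold-change convention reports a ratio r as +r when r >= 1 and -1/r when
r < 1, so a symmetric screen reads "> 1.5 or < -1.5".
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import PipelineConfig, ProteinQuantMatrix
from .errors import StatisticsError

LABEL_UP = "Up"
LABEL_DOWN = "Down"
LABEL_NONE = "none"


def welch_ttest(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Welch t-test between two 2-D arrays (rows x replicates).

    Returns (t, df, p). Degenerate rows (zero variance in both groups) get
    p = 1 when the means agree and p = 0 otherwise, rather than NaN: the
    imputation floor can create exact ties and those must not crash a
    screen of thousands of proteins.
    """
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise StatisticsError("each group needs >= 2 replicates")
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    degenerate = se2 == 0
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, np.sign(diff) * np.inf, t)
        t = np.where(degenerate & (diff == 0), 0.0, t)
    df = np.where(degenerate, na + nb - 2, df)
    with np.errstate(invalid="ignore"):
        p = 2 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate & (diff == 0), 1.0, p)
    p = np.where(degenerate & (diff != 0), 0.0, p)
    return t, df, p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise StatisticsError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def signed_fold_change(log2fc) -> np.ndarray:
    """Map log2 fold-change to the +/- ratio convention (|signed| >= 1)."""
    ratio = np.power(2.0, np.asarray(log2fc, dtype=float))
    return np.where(ratio >= 1, ratio, -1.0 / ratio)


def log2_welch_test(
    proteins: ProteinQuantMatrix,
    group_a: list[str],
    group_b: list[str],
    zero_floor: float,
) -> pd.DataFrame:
    """Contrast group A vs group B per protein on log2 intensities.

    ``zero_floor`` (a small positive intensity, half the low-value
    imputation quantile) replaces non-positive entries before the log2
    transform. Returns a table with linear group means, log2FC, signed_FC,
    t, df and two-tailed p.
    """
    if zero_floor <= 0:
        raise StatisticsError("zero_floor must be positive")
    missing = [s for s in (*group_a, *group_b) if s not in proteins.sample_ids]
    if missing:
        raise StatisticsError(f"unknown sample(s) in contrast: {missing}")
    xa = proteins.intensity[group_a].to_numpy(dtype=float)
    xb = proteins.intensity[group_b].to_numpy(dtype=float)
    la = np.log2(np.maximum(xa, zero_floor))
    lb = np.log2(np.maximum(xb, zero_floor))
    t, df, p = welch_ttest(la, lb)
    log2fc = la.mean(axis=1) - lb.mean(axis=1)
    return pd.DataFrame(
        {
            "mean_a": xa.mean(axis=1),
            "mean_b": xb.mean(axis=1),
            "log2FC": log2fc,
            "signed_FC": signed_fold_change(log2fc),
            "t": t,
            "df": df,
            "p": p,
        },
        index=proteins.protein_ids,
    )


def label_updown(table: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Attach Up/Down labels: Up iff signed_FC > fc_threshold and
    (unadjusted) p < p_threshold; Down symmetric with signed_FC <
    -fc_threshold; otherwise 'none'."""
    out = table.copy()
    up = (out["signed_FC"] > config.fc_threshold) & (out["p"] < config.p_threshold)
    down = (out["signed_FC"] < -config.fc_threshold) & (out["p"] < config.p_threshold)
    out["label"] = np.where(up, LABEL_UP, np.where(down, LABEL_DOWN, LABEL_NONE))
    return out


def differential_table(
    proteins: ProteinQuantMatrix,
    group_a: list[str],
    group_b: list[str],
    config: PipelineConfig,
    zero_floor: float,
) -> pd.DataFrame:
    """Full differential table: Welch contrast + BH adjustment + labels."""
    table = log2_welch_test(proteins, group_a, group_b, zero_floor)
    table["p_adjusted"] = bh_adjust(table["p"].to_numpy())
    return label_updown(table, config)
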