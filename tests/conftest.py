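"""Shared fixtures: small hand-built matrices and designs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from proxidiff.containers import PeptideQuantMatrix, PipelineConfig, SampleDesign
from proxidiff.simulate import make_design


def build_matrix(
    values: dict[str, list[float | None]],
    sample_ids: list[str],
    stage: str = "raw",
) -> PeptideQuantMatrix:
    """Build a matrix from {peptide_id: row}; None marks a missing entry."""
    rows, mask = [], []
    for pid, row in values.items():
        rows.append([0.0 if v is None else float(v) for v in row])
        mask.append([v is not None for v in row])
    idx = pd.Index(list(values), name="peptide_id")
    return PeptideQuantMatrix(
        pd.DataFrame(rows, index=idx, columns=sample_ids),
        pd.DataFrame(mask, index=idx, columns=sample_ids),
        stage=stage,
    )


@pytest.fixture
def design12() -> SampleDesign:
    """The standard 12-sample + 3-SPQC design."""
    return make_design()


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig(seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20250930)
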