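"""Readers and writers for the pipeline's tabular formats.

Peptide tables are TSV/CSV with the peptide id in the first column and one
column per sample. Two missing-value dialects exist and are never
inferred: ``blank_is_missing`` (empty cells are missing, ``0`` is an
observed zero) and ``zero_is_missing`` (both empty cells and ``0`` are
missing). The dialect is explicit because the upstream export mixes true
missingness with deliberately zeroed (misaligned) features, and the two
must stay distinguishable.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import PeptideQuantMatrix, PipelineConfig, SampleDesign
from .errors import FormatError

DIALECTS = ("blank_is_missing", "zero_is_missing")


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _check_rectangular(path: Path, sep: str) -> None:
    # pandas silently NaN-fills short rows; a ragged table must instead be
    # rejected so that truncation is never mistaken for missingness.
    with open(path, encoding="utf-8") as fh:
        widths = {line.rstrip("\n").count(sep) for line in fh if line.strip("\n")}
    if len(widths) > 1:
        raise FormatError(f"ragged rows in {path}")


def read_peptide_table(path: str | Path, dialect: str) -> PeptideQuantMatrix:
    """Read a peptide x sample intensity table at stage ``raw``.

    Parameters
    ----------
    path:
        TSV (default) or ``.csv`` file; header row, first column peptide id.
    dialect:
        ``blank_is_missing`` or ``zero_is_missing``.
    """
    if dialect not in DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}")
    path = Path(path)
    sep = _sep_for(path)
    _check_rectangular(path, sep)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # pragma: no cover - parser-specific messages
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate peptide ids: {dupes[:5]}")
    try:
        values = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric intensity in {path}: {exc}") from exc
    arr = values.to_numpy()
    if np.any(arr[~np.isnan(arr)] < 0):
        raise FormatError("negative intensity")
    observed = ~np.isnan(arr)
    if dialect == "zero_is_missing":
        observed &= arr != 0
    intensity = pd.DataFrame(
        np.where(observed, arr, 0.0), index=df.index, columns=df.columns
    )
    mask = pd.DataFrame(observed, index=df.index, columns=df.columns)
    intensity.index.name = "peptide_id"
    mask.index.name = "peptide_id"
    return PeptideQuantMatrix(intensity, mask, stage="raw")


def write_peptide_table(
    matrix: PeptideQuantMatrix, path: str | Path, dialect: str
) -> None:
    """Write a peptide table; unobserved entries are encoded per dialect.

    Under ``zero_is_missing`` an observed zero cannot be represented (the
    token ``0`` means missing) and is rejected.
    """
    if dialect not in DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}")
    path = Path(path)
    sep = _sep_for(path)
    vals = matrix.intensity.to_numpy(dtype=float)
    obs = matrix.observed.to_numpy(dtype=bool)
    if dialect == "zero_is_missing" and np.any(obs & (vals == 0)):
        raise FormatError("observed zero is not representable under zero_is_missing")
    missing_token = "" if dialect == "blank_is_missing" else "0"
    cells = np.where(obs, np.vectorize(repr)(vals), missing_token)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(sep.join(["peptide_id", *matrix.sample_ids]) + "\n")
        for pid, row in zip(matrix.peptide_ids, cells):
            fh.write(sep.join([str(pid), *row]) + "\n")


def read_design(path: str | Path) -> SampleDesign:
    """Read a sample-design CSV (sample_id, genotype, construct, replicate,
    is_spqc); validation and group semantics live in :class:`SampleDesign`."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty design file {path}") from exc
    if len(df) == 0:
        raise FormatError(f"design file {path} has no samples")
    missing = [c for c in SampleDesign.REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"design is missing columns {missing}")
    df["replicate"] = df["replicate"].fillna("0").astype(int)
    df["is_spqc"] = (
        df["is_spqc"].str.strip().str.lower().map({"true": True, "1": True,
                                                   "false": False, "0": False})
    )
    if df["is_spqc"].isna().any():
        raise FormatError("is_spqc must be True/False or 1/0")
    df["genotype"] = df["genotype"].fillna("")
    df["construct"] = df["construct"].fillna("")
    return SampleDesign(df)


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep=_sep_for(Path(path)), index=False)


def read_peptide_map(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a peptide -> candidate-protein TSV (accessions ';'-separated)."""
    path = Path(path)
    candidates: dict[str, tuple[str, ...]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise FormatError(f"empty map file {path}")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise FormatError(f"bad map row: {line!r}")
            pid, accs = parts
            if pid in candidates:
                raise FormatError(f"duplicate peptide {pid!r} in map")
            acc_tuple = tuple(a for a in accs.split(";") if a)
            if not acc_tuple:
                raise FormatError(f"peptide {pid!r} has no candidate proteins")
            candidates[pid] = acc_tuple
    return candidates


def write_peptide_map(candidates: dict[str, tuple[str, ...]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("peptide_id\tprotein_accessions\n")
        for pid, accs in candidates.items():
            fh.write(f"{pid}\t{';'.join(accs)}\n")


def read_config(path: str | Path) -> PipelineConfig:
    """Read a ``key = value`` config file into a :class:`PipelineConfig`."""
    fields = {f.name: f.type for f in dataclasses.fields(PipelineConfig)}
    kwargs: dict = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"bad config line {line!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise FormatError(f"unknown config key {key!r}")
            if key == "missing_dialect":
                kwargs[key] = value
            elif key in ("n_bins", "seed"):
                kwargs[key] = int(value)
            elif key == "require_contrast_p":
                kwargs[key] = value.lower() in ("true", "1", "yes")
            else:
                kwargs[key] = float(value)
    return PipelineConfig(**kwargs)


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    config: PipelineConfig | None = None,
    float_format: str = "%.10g",
) -> list[str]:
    """Write one TSV per named table plus a run-metadata JSON.

    Output is deterministic: fixed column order (as given), fixed float
    formatting, no timestamps — identical inputs yield byte-identical
    files. Returns the manifest of file names created.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    manifest: list[str] = []
    for name in sorted(tables):
        fname = f"{name}.tsv"
        tables[name].to_csv(out_dir / fname, sep="\t", index=False,
                            float_format=float_format)
        manifest.append(fname)
    meta = {"config": config.to_dict() if config else None, "tables": manifest}
    with open(out_dir / "run_metadata.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest.append("run_metadata.json")
    return manifest
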