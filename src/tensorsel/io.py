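"""Readers, writers and tensor assembly.

Formats: TSV/CSV with a header row and first-column ids; MatrixMarket
(``.mtx``) with ``<path>.rows`` / ``<path>.cols`` sidecar id files; JSON
run manifests; YAML configuration.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import io as sio

from .datatypes import OmicsTensor, SampleDesign

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_design",
    "assemble_tensor",
    "write_manifest",
    "read_config",
]


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("tsv", "txt"):
        return "tsv"
    if suffix == "csv":
        return "csv"
    if suffix == "mtx":
        return "mtx"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format explicitly")


def read_matrix(path, fmt: Optional[str] = None) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a feature x sample matrix; returns (values, row_ids, col_ids).

    TSV/CSV must have a header row of sample ids and feature ids in the
    first column.  MTX input expects ``<path>.rows`` and ``<path>.cols``
    sidecar files with one id per line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)
    if fmt == "mtx":
        mat = sio.mmread(path)
        values = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
        rows = Path(str(path) + ".rows").read_text().split()
        cols = Path(str(path) + ".cols").read_text().split()
        if len(rows) != values.shape[0] or len(cols) != values.shape[1]:
            raise ValueError(
                f"sidecar id counts ({len(rows)}, {len(cols)}) do not match "
                f"matrix shape {values.shape}"
            )
        row_ids, col_ids = rows, cols
    else:
        sep = "\t" if fmt == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        bad = df.apply(pd.to_numeric, errors="coerce")
        if bad.isna().any().any() and not df.isna().any().any():
            r, c = np.argwhere(bad.isna().to_numpy())[0]
            raise ValueError(
                f"non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r}"
            )
        if df.isna().any().any():
            r, c = np.argwhere(df.isna().to_numpy())[0]
            raise ValueError(f"missing value at row {df.index[r]!r}, column {df.columns[c]!r}")
        values = bad.to_numpy(dtype=float)
        row_ids = [str(i) for i in df.index]
        col_ids = [str(c) for c in df.columns]
    if len(set(row_ids)) != len(row_ids):
        raise ValueError("duplicate row identifiers")
    if len(set(col_ids)) != len(col_ids):
        raise ValueError("duplicate column identifiers")
    return values, row_ids, col_ids


def write_matrix(path, values, row_ids, col_ids, fmt: Optional[str] = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    values = np.asarray(values, dtype=float)
    if fmt == "mtx":
        sio.mmwrite(path, np.asarray(values))
        Path(str(path) + ".rows").write_text("\n".join(map(str, row_ids)) + "\n")
        Path(str(path) + ".cols").write_text("\n".join(map(str, col_ids)) + "\n")
        return
    sep = "\t" if fmt == "tsv" else ","
    pd.DataFrame(values, index=list(row_ids), columns=list(col_ids)).to_csv(path, sep=sep)


def read_design(path) -> pd.DataFrame:
    """Read a design sheet with columns sample_id, replicate, condition."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"sample_id", "replicate", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design sheet is missing columns: {sorted(missing)}")
    return df


def assemble_tensor(values, row_ids, col_ids, design: pd.DataFrame) -> OmicsTensor:
    """Rearrange matrix columns into a feature x replicate x condition tensor.

    Every (replicate, condition) cell must occur exactly once among the
    columns; gaps or duplicates are reported explicitly and never imputed.
    Replicate and condition orders follow first appearance in the design
    sheet (conditions are therefore ordinal in sheet order).
    """
    values = np.asarray(values, dtype=float)
    col_pos = {c: i for i, c in enumerate(col_ids)}
    missing_samples = [s for s in design["sample_id"] if s not in col_pos]
    if missing_samples:
        raise ValueError(f"design samples absent from the matrix: {missing_samples}")
    replicates = list(dict.fromkeys(design["replicate"]))
    conditions = list(dict.fromkeys(design["condition"]))
    cell: dict[tuple[str, str], str] = {}
    dupes = []
    for _, row in design.iterrows():
        key = (row["replicate"], row["condition"])
        if key in cell:
            dupes.append(key)
        cell[key] = row["sample_id"]
    if dupes:
        raise ValueError(f"duplicated (replicate, condition) cells: {dupes}")
    gaps = [(r, c) for r in replicates for c in conditions if (r, c) not in cell]
    if gaps:
        raise ValueError(
            f"incomplete replicate x condition grid; missing cells: {gaps}"
        )
    tensor = np.empty((values.shape[0], len(replicates), len(conditions)))
    for j, r in enumerate(replicates):
        for k, c in enumerate(conditions):
            tensor[:, j, k] = values[:, col_pos[cell[(r, c)]]]
    return OmicsTensor(
        values=tensor,
        feature_ids=row_ids,
        mode2_ids=replicates,
        mode3_ids=conditions,
        design=SampleDesign(replicate_labels=replicates, condition_levels=conditions),
    )


def write_manifest(path, manifest: dict) -> None:
    """Write a JSON run manifest (config echo, chosen components, sigmas, seed)."""
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(manifest, indent=2, default=_default) + "\n")


def read_config(path) -> dict:
    """Read a YAML/JSON config (bins, tail_fraction, sigma_bracket, threshold...)."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError("config file must define a mapping")
    return cfg
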