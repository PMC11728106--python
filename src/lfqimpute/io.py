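"""Readers and writers for quantification tables.

The package's own TSV dialect (first column ``protein_id``, one column
per sample, empty cells = missing) with a JSON sidecar holding group
labels, scale, seed and optional ground truth; plus readers for the two
common real-data layouts: MaxQuant ``proteinGroups.txt`` (``LFQ
intensity <sample>`` columns) and FragPipe ``combined_protein.tsv``
(``<sample> MaxLFQ Intensity`` columns), where a zero intensity means
the protein was not quantified.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import IntensityMatrix
from .missingness import MAR, MNAR, OBSERVED, STATUS_NAMES, CellMask
from .synthetic import GroundTruth

_MISSING_TOKENS = {"", "na", "nan"}


# ---------------------------------------------------------------------------
# native TSV dialect
# ---------------------------------------------------------------------------

def write_matrix_tsv(m: IntensityMatrix, path: str | Path,
                     seed: int | None = None,
                     ground_truth: GroundTruth | None = None) -> None:
    """Write matrix as TSV plus a ``<path>.json`` sidecar with metadata."""
    path = Path(path)
    df = m.to_frame()
    df.index.name = "protein_id"
    df.to_csv(path, sep="\t", na_rep="", float_format="%.17g")
    sidecar = {
        "group_labels": m.group_labels,
        "scale": m.scale,
        "seed": seed,
    }
    if ground_truth is not None:
        sidecar["ground_truth"] = {
            "de_flags": ground_truth.de_flags.astype(int).tolist(),
            "true_log2_fc": ground_truth.true_log2_fc.tolist(),
        }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_matrix_tsv(path: str | Path, zeros_as_missing: bool = False) -> IntensityMatrix:
    """Read the native TSV dialect; uses the JSON sidecar when present."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "protein_id":
        raise ValueError("first column must be 'protein_id'")
    ids = df["protein_id"].tolist()
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise ValueError(f"duplicate protein id {dup!r}")
    sample_ids = list(df.columns[1:])
    values = np.empty((len(ids), len(sample_ids)))
    for j, col in enumerate(sample_ids):
        for i, cell in enumerate(df[col].tolist()):
            token = "" if cell is None or (isinstance(cell, float) and np.isnan(cell)) \
                else str(cell).strip()
            if token.lower() in _MISSING_TOKENS:
                values[i, j] = np.nan
                continue
            try:
                v = float(token)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell at row {ids[i]!r}, column {col!r}: {token!r}"
                ) from None
            values[i, j] = np.nan if (zeros_as_missing and v == 0) else v

    sidecar_path = Path(str(path) + ".json")
    group_labels = sample_ids
    scale = "raw"
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        group_labels = meta.get("group_labels", sample_ids)
        scale = meta.get("scale", "raw")
    return IntensityMatrix(values, ids, sample_ids, group_labels, scale=scale)


def read_sidecar_ground_truth(path: str | Path) -> GroundTruth | None:
    meta_path = Path(str(path) + ".json")
    if not meta_path.exists():
        return None
    meta = json.loads(meta_path.read_text())
    gt = meta.get("ground_truth")
    if gt is None:
        return None
    return GroundTruth(np.array(gt["de_flags"], dtype=bool),
                       np.array(gt["true_log2_fc"], dtype=float))


def write_mask_tsv(mask: CellMask, protein_ids: list[str], sample_ids: list[str],
                   path: str | Path) -> None:
    """Persist a mask as long-format TSV (protein_id, sample_id, status)."""
    rows = []
    for i, pid in enumerate(protein_ids):
        for j, sid in enumerate(sample_ids):
            rows.append((pid, sid, STATUS_NAMES[int(mask.status[i, j])]))
    pd.DataFrame(rows, columns=["protein_id", "sample_id", "status"]).to_csv(
        path, sep="\t", index=False)


def read_mask_tsv(path: str | Path, protein_ids: list[str],
                  sample_ids: list[str]) -> CellMask:
    df = pd.read_csv(path, sep="\t")
    codes = {v: k for k, v in STATUS_NAMES.items()}
    status = np.zeros((len(protein_ids), len(sample_ids)), dtype=np.int8)
    pi = {p: i for i, p in enumerate(protein_ids)}
    si = {s: j for j, s in enumerate(sample_ids)}
    for pid, sid, name in df.itertuples(index=False):
        status[pi[pid], si[sid]] = codes[name]
    return CellMask(status)


# ---------------------------------------------------------------------------
# real-data layouts
# ---------------------------------------------------------------------------

_MQ_FILTER_COLUMNS = ("Reverse", "Potential contaminant", "Only identified by site")


def read_maxquant_proteingroups(path: str | Path) -> IntensityMatrix:
    """MaxQuant proteinGroups.txt -> matrix of the ``LFQ intensity`` columns.

    Rows flagged '+' in Reverse / Potential contaminant / Only
    identified by site are dropped; zero intensities become missing.
    """
    df = pd.read_csv(path, sep="\t")
    lfq_cols = [c for c in df.columns if c.startswith("LFQ intensity ")]
    if not lfq_cols:
        raise ValueError("no 'LFQ intensity <sample>' columns found")
    for col in _MQ_FILTER_COLUMNS:
        if col in df.columns:
            df = df[df[col].fillna("") != "+"]
    id_col = "Majority protein IDs" if "Majority protein IDs" in df.columns \
        else df.columns[0]
    ids = df[id_col].astype(str).tolist()
    values = df[lfq_cols].to_numpy(dtype=float)
    values[values == 0] = np.nan
    sample_ids = [c[len("LFQ intensity "):] for c in lfq_cols]
    return IntensityMatrix(values, ids, sample_ids, sample_ids, scale="raw")


def read_fragpipe_combined(path: str | Path) -> IntensityMatrix:
    """FragPipe combined_protein.tsv -> matrix of the ``MaxLFQ Intensity`` columns."""
    df = pd.read_csv(path, sep="\t")
    lfq_cols = [c for c in df.columns if c.endswith(" MaxLFQ Intensity")]
    if not lfq_cols:
        raise ValueError("no '<sample> MaxLFQ Intensity' columns found")
    id_col = next((c for c in ("Protein", "Protein ID") if c in df.columns),
                  df.columns[0])
    ids = df[id_col].astype(str).tolist()
    values = df[lfq_cols].to_numpy(dtype=float)
    values[values == 0] = np.nan
    sample_ids = [c[: -len(" MaxLFQ Intensity")] for c in lfq_cols]
    return IntensityMatrix(values, ids, sample_ids, sample_ids, scale="raw")
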