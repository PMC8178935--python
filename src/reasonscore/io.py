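"""Delimited-text I/O with range validation.

All pipeline intermediates are plain TSV/JSON so every stage can be audited
and re-run from persisted files.  Matrices are probes/genes x samples with
the row id in the first column and sample ids in the header.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .containers import MethylationDataset, validate_manifest

_MATRIX_KINDS = {
    "beta": dict(lo=0.0, hi=1.0, integer=False),
    "detection_p": dict(lo=0.0, hi=1.0, integer=False),
    "counts": dict(lo=0.0, hi=np.inf, integer=True),
}

#: Clinical table columns expected by the scoring stages.
CLINICAL_COLUMNS = (
    "age",
    "sex",
    "race",
    "ethnicity",
    "tobacco",
    "alcohol",
    "site",
    "grade",
    "stage",
    "pni",
    "lvi",
    "margin",
    "vital_status_5yr",
)


def read_matrix(path: str | Path, kind: str) -> pd.DataFrame:
    """Read a probes/genes x samples matrix and validate its value range.

    Parameters
    ----------
    path
        Tab-delimited file; first column row ids, header row sample ids.
    kind
        One of ``"beta"``, ``"detection_p"``, ``"counts"``.

    Raises
    ------
    ValueError
        On duplicated ids, non-numeric cells, or out-of-range values; the
        error names the offending row and column.
    """
    if kind not in _MATRIX_KINDS:
        raise ValueError(f"unknown matrix kind {kind!r}; expected one of {sorted(_MATRIX_KINDS)}")
    spec = _MATRIX_KINDS[kind]
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"{path}: duplicated row ids {dups}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()[:5]
        raise ValueError(f"{path}: duplicated sample ids {dups}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell in matrix ({exc})") from exc
    bad = ~np.isfinite(values) | (values < spec["lo"]) | (values > spec["hi"])
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"{path}: value {values[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r} outside [{spec['lo']}, {spec['hi']}] for kind {kind!r}"
        )
    if spec["integer"] and not np.allclose(values, np.round(values)):
        i, j = map(int, np.argwhere(values != np.round(values))[0])
        raise ValueError(
            f"{path}: non-integer count {values[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    if spec["integer"]:
        df = df.astype(np.int64)
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=True)


def read_manifest(path: str | Path) -> pd.DataFrame:
    return validate_manifest(pd.read_csv(path, sep="\t", dtype={"chrom": str}))


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    out = manifest.copy()
    out["snp_flag"] = out["snp_flag"].astype(int)
    out["cross_reactive_flag"] = out["cross_reactive_flag"].astype(int)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=True, index_label="probe_id")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read the clinical cohort table indexed by patient id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"{path}: duplicated patient ids {dups}")
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: clinical table lacks columns {missing}")
    vals = set(pd.unique(df["vital_status_5yr"].dropna()))
    if not vals <= {0, 1}:
        raise ValueError(f"{path}: vital_status_5yr must be 0/1, got {sorted(vals)[:5]}")
    return df


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=True, index_label="patient_id")


def read_dataset(
    beta_path: str | Path,
    detection_p_path: str | Path,
    clinical_path: str | Path,
) -> MethylationDataset:
    """Assemble a :class:`MethylationDataset` from its three files."""
    beta = read_matrix(beta_path, "beta")
    detp = read_matrix(detection_p_path, "detection_p")
    clinical = read_clinical(clinical_path)
    return MethylationDataset(beta=beta, detection_p=detp, outcome=clinical["vital_status_5yr"])


def dataset_from_beta(beta_path: str | Path, clinical_path: str | Path) -> MethylationDataset:
    """Dataset for post-detection stages: beta + outcome, all-pass detection p."""
    beta = read_matrix(beta_path, "beta")
    clinical = read_clinical(clinical_path)
    detp = pd.DataFrame(
        np.zeros(beta.shape), index=beta.index, columns=beta.columns
    )
    return MethylationDataset(beta=beta, detection_p=detp, outcome=clinical["vital_status_5yr"])


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: one set per line (name, description, genes)."""
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
        name, _desc, *genes = parts
        genes = [g for g in genes if g]
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicated gene-set name {name!r}")
        sets[name] = genes
    if not sets:
        raise ValueError(f"{path}: empty GMT file")
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    lines = [f"{name}\tna\t" + "\t".join(genes) for name, genes in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
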