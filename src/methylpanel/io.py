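"""Readers and writers for the pipeline's plain-text formats.

Beta matrices are TSV with probes as rows (index column ``probe_id``) and
sample ids as header; sample sheets are CSV; gene sets are GMT
(term, description, genes... tab-separated).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = [
    "read_beta",
    "write_beta",
    "read_samples",
    "read_annotation",
    "read_gmt",
    "write_gmt",
    "read_truth",
]


def read_beta(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "probe_id"
    bad = df.stack(future_stack=True).dropna()
    if ((bad < 0) | (bad > 1)).any():
        raise ValueError(f"beta values outside [0, 1] in {path}")
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError(f"duplicate probe or sample ids in {path}")
    return df


def write_beta(beta: pd.DataFrame, path: str | Path) -> None:
    beta.to_csv(path, sep="\t", index_label="probe_id")


def read_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "patient_id": str})
    required = {"sample_id", "specimen_type", "disease_label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in sample sheet")
    if "age" in df.columns and (df["age"].dropna() <= 0).any():
        raise ValueError("ages must be positive")
    return df


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"probe_id", "gene", "region_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    return df


def read_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    collection: dict[str, tuple[str, frozenset[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        term_id, label, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if term_id in collection:
            raise ValueError(f"duplicate term id {term_id!r}")
        if not genes:
            raise ValueError(f"empty gene set for term {term_id!r}")
        collection[term_id] = (label, frozenset(genes))
    return collection


def write_gmt(collection: dict[str, tuple[str, frozenset[str]]], path: str | Path) -> None:
    lines = []
    for term_id, (label, genes) in collection.items():
        lines.append("\t".join([term_id, label, *sorted(genes)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
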