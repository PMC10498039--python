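"""Plain-text readers and writers for the pipeline's tabular artifacts.

Conventions: intensity and normalized matrices are TSV with proteins as
rows and sample IDs as columns, an empty cell marking a missing value;
designs and tissue tables are TSV with their ID column as index; ID
lists are one ID per line; gene sets use the GMT format (set name,
description, then tab-separated member IDs); ground truth and reports
serialize to JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .harmonize import ImputationReport
from .synth import GroundTruth

__all__ = [
    "write_matrix_tsv", "read_matrix_tsv",
    "write_design_tsv", "read_design_tsv",
    "write_id_list", "read_id_list",
    "write_gmt", "read_gmt",
    "write_ground_truth_json", "write_imputation_report_json",
]


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", index_label="protein_id", na_rep="")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="protein_id")


def write_design_tsv(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index_label="sample_id")


def read_design_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_id_list(ids, path: str | Path) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in sorted(ids)))


def read_id_list(path: str | Path) -> frozenset[str]:
    lines = Path(path).read_text().splitlines()
    return frozenset(line.strip() for line in lines if line.strip())


def write_gmt(gene_sets: dict[str, set[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            members = "\t".join(sorted(gene_sets[name]))
            fh.write(f"{name}\t{descriptions.get(name, 'na')}\t{members}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets[fields[0]] = {f for f in fields[2:] if f}
    return sets


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    return obj


def write_ground_truth_json(truth: GroundTruth, path: str | Path) -> None:
    payload = {f.name: _jsonable(getattr(truth, f.name))
               for f in dataclasses.fields(truth)}
    Path(path).write_text(json.dumps(payload))


def write_imputation_report_json(report: ImputationReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(dataclasses.asdict(report))))
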