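"""Readers and writers for the pipeline's plain-text interchange formats.

Matrices are TSV with probe rows and a header of sample ids; sample
sheets are CSV (sample_id, group, optional covariates); annotation is a
BED-like TSV; gene sets are standard GMT; reports and ground truth are
JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GroundTruth, MethylationDataset, validate_annotation


def write_matrix(values: pd.DataFrame, path) -> None:
    values.to_csv(path, sep="\t", index_label="probe_id")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id")


def write_sample_sheet(group: pd.Series, path, covariates: pd.DataFrame | None = None) -> None:
    df = pd.DataFrame({"group": group})
    if covariates is not None:
        df = df.join(covariates)
    df.to_csv(path, index_label="sample_id")


def read_sample_sheet(path) -> tuple[pd.Series, pd.DataFrame | None]:
    df = pd.read_csv(path, index_col="sample_id")
    group = df["group"]
    cov = df.drop(columns=["group"])
    return group, (cov if cov.shape[1] else None)


def write_annotation(annotation: pd.DataFrame, path) -> None:
    """BED-like TSV: chrom, start, end, probe_id, gene, island_relation, flags."""
    out = pd.DataFrame(
        {
            "chrom": annotation["chromosome"],
            "start": annotation["position"],
            "end": annotation["position"],
            "probe_id": annotation.index,
            "gene": annotation["gene"],
            "island_relation": annotation["island_relation"],
            "flags": [";".join(sorted(f)) for f in annotation["flags"]],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", keep_default_na=False)
    ann = pd.DataFrame(
        {
            "chromosome": raw["chrom"],
            "position": raw["start"],
            "island_relation": raw["island_relation"],
            "gene": raw["gene"],
            "flags": [
                frozenset(f.split(";")) if f else frozenset() for f in raw["flags"]
            ],
        },
    )
    ann.index = pd.Index(raw["probe_id"], name="probe_id")
    validate_annotation(ann)
    return ann


def write_gmt(gene_sets: dict, path, descriptions: dict | None = None) -> None:
    with open(path, "w") as fh:
        for set_id in sorted(gene_sets):
            desc = (descriptions or {}).get(set_id, "na")
            genes = "\t".join(gene_sets[set_id])
            fh.write(f"{set_id}\t{desc}\t{genes}\n")


def read_gmt(path) -> dict:
    sets = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets[fields[0]] = sorted(fields[2:])
    return sets


def write_ground_truth(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_jsonable(), fh, indent=1)


def read_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        return GroundTruth.from_jsonable(json.load(fh))


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_default)


def read_dataset(matrix_path, sample_sheet_path, annotation_path, scale: str) -> MethylationDataset:
    values = read_matrix(matrix_path)
    group, _ = read_sample_sheet(sample_sheet_path)
    annotation = read_annotation(annotation_path)
    return MethylationDataset(values=values, group=group, annotation=annotation,
                              scale=scale)


def write_sparse_incidence(M, path) -> None:
    """Coordinate TSV of a binary incidence matrix (row_id, col_id)."""
    B = M.values.to_numpy()
    rows, cols = np.nonzero(B)
    pd.DataFrame(
        {
            "dmp_id": M.values.index[rows],
            "cpg_id": M.values.columns[cols],
        }
    ).to_csv(path, sep="\t", index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
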