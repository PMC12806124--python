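"""Readers and writers for the plain-text formats the pipeline consumes.

TSV expression matrices carry gene IDs in the first column and one sample
per remaining column.  Single-cell counts travel as a MatrixMarket triplet
(matrix.mtx + genes.tsv + barcodes.tsv).  Gene sets use GMT
(name <tab> description <tab> member...).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .containers import ExpressionMatrix, GeneSet, TissueDesign
from .exceptions import ValidationError


def read_expression_tsv(path, unit_scale: str = "linear") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return ExpressionMatrix.from_frame(df, unit_scale=unit_scale)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t")


def read_design_tsv(path) -> TissueDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("design TSV needs sample_id and tissue columns")
    return TissueDesign(pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0]))


def write_design_tsv(design: TissueDesign, path) -> None:
    design.labels.rename("tissue").to_frame().to_csv(path, sep="\t")


def read_gmt(path) -> dict[str, GeneSet]:
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"malformed GMT line: {line[:80]!r}")
            name, desc, members = fields[0], fields[1], fields[2:]
            sets[name] = GeneSet(name=name, members=tuple(m for m in members if m),
                                 description=desc)
    if not sets:
        raise ValidationError("GMT file contains no gene sets")
    return sets


def write_gmt(sets: Mapping[str, GeneSet] | list[GeneSet], path) -> None:
    if isinstance(sets, Mapping):
        sets = list(sets.values())
    with open(path, "w") as fh:
        for gs in sets:
            desc = gs.description or "na"
            fh.write("\t".join([gs.name, desc, *gs.members]) + "\n")


def write_mtx_bundle(matrix: ExpressionMatrix, directory, prefix: str = "sc") -> list[Path]:
    """Write counts as MatrixMarket + gene/barcode sidecars; returns paths."""
    directory = Path(directory)
    mtx = directory / f"{prefix}_matrix.mtx"
    genes = directory / f"{prefix}_genes.tsv"
    barcodes = directory / f"{prefix}_barcodes.tsv"
    sio.mmwrite(str(mtx), sp.csr_matrix(matrix.values))
    genes.write_text("\n".join(matrix.gene_ids) + "\n")
    barcodes.write_text("\n".join(matrix.sample_ids) + "\n")
    return [mtx, genes, barcodes]


def read_mtx_bundle(directory, prefix: str = "sc",
                    unit_scale: str = "linear") -> ExpressionMatrix:
    directory = Path(directory)
    values = sio.mmread(str(directory / f"{prefix}_matrix.mtx"))
    gene_ids = (directory / f"{prefix}_genes.tsv").read_text().split()
    sample_ids = (directory / f"{prefix}_barcodes.tsv").read_text().split()
    return ExpressionMatrix(values, gene_ids, sample_ids, unit_scale=unit_scale)


def read_survival_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    need = {"subject_id", "time", "event"}
    if not need.issubset(df.columns):
        raise ValidationError(f"survival TSV must have columns {sorted(need)}")
    return df


def write_survival_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_scores_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return pd.Series(df["score"].to_numpy(dtype=float),
                     index=df.iloc[:, 0].astype(str), name="score")


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (set, frozenset, tuple)):
            return sorted(o) if isinstance(o, (set, frozenset)) else list(o)
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
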