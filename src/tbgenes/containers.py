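"""Core in-memory containers.

The central object is :class:`ExpressionMatrix`, a genes x samples abundance
matrix with an explicit unit scale (``linear`` abundances or ``log2``
transformed values).  Keeping the scale on the object lets downstream
operations decide whether to de-log (fold changes are ratios of linear
group means) or to log-transform (z-score signature scoring).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .exceptions import DesignError, GeneSetError, ValidationError

UNIT_SCALES = ("linear", "log2")


class ExpressionMatrix:
    """Genes x samples expression matrix with a declared unit scale.

    Parameters
    ----------
    values
        2-D array-like (dense or scipy sparse), shape (n_genes, n_samples).
        Stored densely as float64.
    gene_ids, sample_ids
        Unique identifiers for rows and columns.
    unit_scale
        ``"linear"`` (non-negative abundances, e.g. TPM or counts) or
        ``"log2"`` (already log2-transformed values).
    """

    def __init__(self, values, gene_ids: Sequence[str], sample_ids: Sequence[str],
                 unit_scale: str = "linear"):
        if sp.issparse(values):
            values = values.toarray()
        values = np.asarray(values, dtype=np.float64)
        if values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        gene_ids = pd.Index([str(g) for g in gene_ids], name="gene_id")
        sample_ids = pd.Index([str(s) for s in sample_ids], name="sample_id")
        if values.shape != (len(gene_ids), len(sample_ids)):
            raise ValidationError(
                f"shape {values.shape} does not match {len(gene_ids)} genes x "
                f"{len(sample_ids)} samples")
        if not gene_ids.is_unique:
            raise ValidationError("duplicate gene IDs")
        if not sample_ids.is_unique:
            raise ValidationError("duplicate sample IDs")
        if unit_scale not in UNIT_SCALES:
            raise ValidationError(f"unit_scale must be one of {UNIT_SCALES}")
        if not np.all(np.isfinite(values)):
            raise ValidationError("expression values must be finite")
        if unit_scale == "linear" and (values < 0).any():
            raise ValidationError("linear-scale expression must be non-negative")
        self.values = values
        self.gene_ids = gene_ids
        self.sample_ids = sample_ids
        self.unit_scale = unit_scale

    # ------------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def linear_values(self) -> np.ndarray:
        """Values on the linear abundance scale (de-logged if needed)."""
        if self.unit_scale == "linear":
            return self.values
        return np.exp2(self.values)

    def log2_values(self, pseudocount: float = 1.0) -> np.ndarray:
        """Values on the log2 scale; linear input gets log2(x + pseudocount)."""
        if self.unit_scale == "log2":
            return self.values
        return np.log2(self.values + pseudocount)

    def subset(self, genes: Iterable[str] | None = None,
               samples: Iterable[str] | None = None) -> "ExpressionMatrix":
        gi = self.gene_ids if genes is None else pd.Index(list(genes))
        si = self.sample_ids if samples is None else pd.Index(list(samples))
        missing = gi.difference(self.gene_ids)
        if len(missing):
            raise ValidationError(f"genes not in matrix: {list(missing)[:5]}")
        missing = si.difference(self.sample_ids)
        if len(missing):
            raise ValidationError(f"samples not in matrix: {list(missing)[:5]}")
        ridx = self.gene_ids.get_indexer(gi)
        cidx = self.sample_ids.get_indexer(si)
        return ExpressionMatrix(self.values[np.ix_(ridx, cidx)], gi, si,
                                self.unit_scale)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, unit_scale: str = "linear") -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=np.float64), df.index, df.columns, unit_scale)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} "
                f"samples, scale={self.unit_scale!r})")


class TissueDesign:
    """Mapping from sample ID to tissue label.

    At least two tissues are required; per-operation sample-size
    requirements (e.g. >= 2 samples per tissue for rank tests) are checked
    where they matter.
    """

    def __init__(self, labels: Mapping[str, str] | pd.Series):
        s = pd.Series(labels, dtype=object)
        s.index = s.index.astype(str)
        s.index.name = "sample_id"
        s.name = "tissue"
        if not s.index.is_unique:
            raise DesignError("duplicate sample IDs in design")
        if s.isna().any():
            raise DesignError("missing tissue labels")
        if s.nunique() < 2:
            raise DesignError("design must contain at least two tissues")
        self.labels = s.astype(str)

    @property
    def tissues(self) -> list[str]:
        return sorted(self.labels.unique())

    def samples_for(self, tissue: str) -> pd.Index:
        if tissue not in set(self.labels):
            raise DesignError(f"unknown tissue {tissue!r}")
        return self.labels.index[self.labels == tissue]

    def align_to(self, matrix: ExpressionMatrix) -> pd.Series:
        """Labels reindexed to the matrix sample order; every sample must be labeled."""
        missing = matrix.sample_ids.difference(self.labels.index)
        if len(missing):
            raise DesignError(f"samples without tissue label: {list(missing)[:5]}")
        return self.labels.reindex(matrix.sample_ids)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (one GMT row)."""

    name: str
    members: tuple[str, ...]
    description: str = ""

    def __post_init__(self):
        members = tuple(dict.fromkeys(str(m) for m in self.members))
        if not members:
            raise GeneSetError(f"gene set {self.name!r} is empty")
        object.__setattr__(self, "members", members)

    def intersect(self, gene_ids: Iterable[str]) -> tuple[str, ...]:
        present = set(gene_ids)
        return tuple(m for m in self.members if m in present)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ScoreVector:
    """One signature score per sample/cell for a named gene set."""

    scores: pd.Series
    method: str
    gene_set: str
    n_genes_used: int
    degenerate_genes: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if not np.all(np.isfinite(self.scores.to_numpy(dtype=float))):
            raise ValidationError("scores must be finite")

    def to_frame(self) -> pd.DataFrame:
        df = self.scores.rename("score").to_frame()
        df["method"] = self.method
        df["gene_set"] = self.gene_set
        return df.reset_index(names="sample_id")

    def __len__(self) -> int:
        return len(self.scores)
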