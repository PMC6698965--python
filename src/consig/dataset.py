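"""Core data carriers: two-cohort expression datasets and gene signatures.

An :class:`ExpressionDataset` holds a genes x samples matrix together with a
binary case/control label per sample and a study identifier.  It is the
universal carrier through the pipeline: preprocessing, feature selection and
cross-study evaluation all consume and produce this type.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CASE = 1
CONTROL = 0

__all__ = ["ExpressionDataset", "Signature", "CASE", "CONTROL"]


class FormatError(ValueError):
    """Raised when an input file or table violates the expected format."""


@dataclass
class ExpressionDataset:
    """A two-cohort expression dataset.

    Parameters
    ----------
    matrix
        Genes x samples real-valued expression table.  Row index are gene
        (or probe) identifiers, columns are sample identifiers.
    labels
        Per-sample cohort assignment, indexed by sample id; 1 = case,
        0 = control.
    study_id
        Identifier of the originating study.
    platform_id
        Optional platform/chip identifier.
    is_log_scale
        Whether the matrix is on a log2 scale (set by preprocessing).
    """

    matrix: pd.DataFrame
    labels: pd.Series
    study_id: str
    platform_id: str | None = None
    is_log_scale: bool = False

    def __post_init__(self) -> None:
        if not self.matrix.columns.is_unique:
            dup = self.matrix.columns[self.matrix.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        self.labels = self.labels.reindex(self.matrix.columns)
        if self.labels.isna().any():
            missing = self.labels.index[self.labels.isna()].tolist()
            raise FormatError(f"samples missing from metadata: {missing}")
        if self.matrix.isna().any().any():
            raise FormatError("expression matrix contains missing values")
        bad = set(self.labels.unique()) - {CASE, CONTROL}
        if bad:
            raise FormatError(f"labels must be 0/1, found {sorted(bad)}")
        if (self.labels == CASE).sum() == 0 or (self.labels == CONTROL).sum() == 0:
            raise FormatError("both cohorts (case and control) must be non-empty")
        self.labels = self.labels.astype(int)

    # -- basic views -------------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    @property
    def case_ids(self) -> list[str]:
        return list(self.labels.index[self.labels == CASE])

    @property
    def control_ids(self) -> list[str]:
        return list(self.labels.index[self.labels == CONTROL])

    def has_duplicate_genes(self) -> bool:
        return bool(self.matrix.index.duplicated().any())

    # -- subsetting --------------------------------------------------------

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        """Restrict to ``genes`` (kept in the given order)."""
        missing = [g for g in genes if g not in self.matrix.index]
        if missing:
            raise KeyError(f"genes absent from dataset: {missing[:5]}")
        return dataclasses.replace(self, matrix=self.matrix.loc[list(genes)])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionDataset":
        """Restrict to ``samples`` (kept in the given order)."""
        missing = [s for s in samples if s not in self.matrix.columns]
        if missing:
            raise KeyError(f"samples absent from dataset: {missing[:5]}")
        return ExpressionDataset(
            matrix=self.matrix[list(samples)],
            labels=self.labels.loc[list(samples)],
            study_id=self.study_id,
            platform_id=self.platform_id,
            is_log_scale=self.is_log_scale,
        )

    def values(self) -> np.ndarray:
        """Samples x genes float array (the orientation classifiers expect)."""
        return self.matrix.to_numpy(dtype=float).T

    def label_array(self) -> np.ndarray:
        return self.labels.to_numpy(dtype=int)


@dataclass(frozen=True)
class Signature:
    """An unordered gene set with provenance.

    Genes are stored as a sorted tuple so two signatures with the same
    members compare equal and serialize identically.  ``provenance`` records
    how the signature was produced (method name, study id, master seed,
    group indices or per-gene vote counts).
    """

    genes: tuple[str, ...]
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __init__(self, genes: Iterable[str], provenance: Mapping[str, object] | None = None):
        object.__setattr__(self, "genes", tuple(sorted(set(genes))))
        object.__setattr__(self, "provenance", dict(provenance or {}))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)

    @property
    def is_empty(self) -> bool:
        return len(self.genes) == 0

    def jaccard(self, other: "Signature") -> float:
        a, b = self.gene_set, other.gene_set
        if not a and not b:
            return 1.0
        return len(a & b) / len(a | b)
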