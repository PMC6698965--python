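"""Linear SVM training, squared-weight gene ranking and plain SVM-RFE.

The recursive feature elimination criterion is the classical one: train a
soft-margin linear SVM, score each gene by the square of its weight in the
decision function, and discard the lowest-scoring genes.  Genes are
standardized to zero mean / unit variance using training-data statistics
only; the same transform is applied to any test data, so no information
leaks from the test half.  Constant genes (zero training variance) are
mapped to an all-zero column and therefore receive an exactly-zero weight.

The quadratic program is solved by libsvm (``sklearn.svm.SVC`` with a
linear kernel), which is deterministic for a fixed input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.svm import SVC

from .dataset import ExpressionDataset, Signature

__all__ = [
    "LinearModel",
    "GeneRanking",
    "train_linear_svm",
    "rank_genes",
    "plain_svm_rfe",
    "evaluate_accuracy",
]


@dataclass
class LinearModel:
    """A fitted linear SVM on standardized gene expression.

    ``w`` and ``b`` act on the standardized scale: the decision value of a
    sample ``x`` is ``w . z + b`` with ``z = (x - mean) / std`` (std of a
    constant gene is replaced by 1, making its standardized value 0).
    """

    genes: tuple[str, ...]
    w: np.ndarray
    b: float
    C: float
    mean: np.ndarray = field(repr=False)
    std: np.ndarray = field(repr=False)
    train_accuracy: float = float("nan")

    def transform(self, ds: ExpressionDataset) -> np.ndarray:
        """Standardize ``ds`` (restricted to the model's genes) with the
        training-set parameters."""
        x = ds.subset_genes(list(self.genes)).values()
        return (x - self.mean) / self.std

    def decision_values(self, ds: ExpressionDataset) -> np.ndarray:
        return self.transform(ds) @ self.w + self.b

    def predict(self, ds: ExpressionDataset) -> np.ndarray:
        """Predicted labels (1 = case) for the samples of ``ds``."""
        return (self.decision_values(ds) > 0).astype(int)

    def to_record(self) -> dict:
        return {
            "genes": list(self.genes),
            "w": self.w.tolist(),
            "b": self.b,
            "C": self.C,
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
            "train_accuracy": self.train_accuracy,
        }

    @classmethod
    def from_record(cls, rec: dict) -> "LinearModel":
        return cls(
            genes=tuple(rec["genes"]),
            w=np.asarray(rec["w"], dtype=float),
            b=float(rec["b"]),
            C=float(rec["C"]),
            mean=np.asarray(rec["mean"], dtype=float),
            std=np.asarray(rec["std"], dtype=float),
            train_accuracy=float(rec["train_accuracy"]),
        )


@dataclass(frozen=True)
class GeneRanking:
    """Genes ordered from highest to lowest ranking criterion c_i = w_i^2.

    Ties are broken lexicographically by gene id, so the order is a
    deterministic permutation of the model's genes.
    """

    order: tuple[str, ...]
    criteria: dict[str, float] = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.order)

    def bottom_half(self) -> frozenset[str]:
        """The floor(n/2) lowest-criterion genes."""
        k = self.n // 2
        return frozenset(self.order[self.n - k :]) if k else frozenset()


def train_linear_svm(ds: ExpressionDataset, C: float = 1.0) -> LinearModel:
    """Fit a soft-margin linear SVM on ``ds`` (case=+1 vs control=-1)."""
    y = ds.label_array()
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    x = ds.values()
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std_safe = np.where(std > 0, std, 1.0)
    z = (x - mean) / std_safe

    clf = SVC(kernel="linear", C=C)
    clf.fit(z, y)
    w = clf.coef_.ravel().astype(float)
    b = float(clf.intercept_[0])
    train_acc = float((clf.predict(z) == y).mean())
    return LinearModel(
        genes=tuple(ds.gene_ids),
        w=w,
        b=b,
        C=C,
        mean=mean,
        std=std_safe,
        train_accuracy=train_acc,
    )


def rank_genes(model: LinearModel) -> GeneRanking:
    """Rank the model's genes by squared weight, descending."""
    criteria = {g: float(w * w) for g, w in zip(model.genes, model.w)}
    order = tuple(sorted(criteria, key=lambda g: (-criteria[g], g)))
    return GeneRanking(order=order, criteria=criteria)


def plain_svm_rfe(
    ds: ExpressionDataset,
    elim_fraction: float = 0.5,
    C: float = 1.0,
    return_rounds: bool = False,
) -> list[str] | tuple[list[str], list[list[str]]]:
    """Single-split recursive feature elimination.

    Repeatedly trains on all samples of ``ds``, ranks genes by squared
    weight, and removes the bottom ``ceil(elim_fraction * remaining)``
    genes until one gene remains.  Returns the full elimination order,
    first-eliminated first; the surviving gene is last.  Within a round,
    genes leave worst-ranked first.  With ``return_rounds`` the per-round
    eliminated lists are returned as well.
    """
    if not 0 < elim_fraction < 1:
        raise ValueError("elim_fraction must be in (0, 1)")
    surviving = sorted(ds.gene_ids)
    eliminated: list[str] = []
    rounds: list[list[str]] = []
    while len(surviving) > 1:
        ranking = rank_genes(train_linear_svm(ds.subset_genes(surviving), C=C))
        n_drop = min(math.ceil(elim_fraction * len(surviving)), len(surviving) - 1)
        doomed = list(reversed(ranking.order[len(surviving) - n_drop :]))
        eliminated.extend(doomed)  # worst-ranked leaves first
        rounds.append(doomed)
        surviving = sorted(ranking.order[: len(surviving) - n_drop])
    eliminated.extend(surviving)
    if return_rounds:
        return eliminated, rounds
    return eliminated


def evaluate_accuracy(
    model_or_signature: LinearModel | Signature | Iterable[str],
    train_ds: ExpressionDataset,
    test_ds: ExpressionDataset,
    C: float = 1.0,
) -> float:
    """Fraction of ``test_ds`` samples classified correctly.

    Given a gene set, a model is first trained on ``train_ds`` restricted
    to those genes (standardization from the training data only).  Every
    signature gene must be present in the test data.
    """
    if isinstance(model_or_signature, LinearModel):
        model = model_or_signature
    else:
        genes = sorted(model_or_signature)
        missing = [g for g in genes if g not in test_ds.matrix.index]
        if missing:
            raise KeyError(f"signature genes absent from test data: {missing[:5]}")
        model = train_linear_svm(train_ds.subset_genes(genes), C=C)
    pred = model.predict(test_ds)
    return float((pred == test_ds.label_array()).mean())
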