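"""Cross-study reproducibility metrics.

Four instruments quantify how reproducible a feature-selection method's
signatures are across independent studies:

* **Consistency score (CS)** — the total number of agreeing signature
  pairs: for each gene appearing in ``m_g`` of the signatures it
  contributes ``C(m_g, 2)``; equivalently the sum of pairwise
  intersection sizes over all signature pairs.
* **Cross-study prediction** — an SVM trained on one study restricted to
  a signature (C tuned by stratified five-fold CV on the training study
  only) predicts the case/control status of another study; performance is
  summarized by accuracy (ACC) and the Matthews correlation coefficient
  (MCC).
* **Random-effects odds ratios** — per study, a 2x2 table of
  correct/incorrect predictions under two competing methods gives an odds
  ratio; study ORs are pooled with the DerSimonian-Laird random-effects
  model into a forest table.
* **Hypergeometric enrichment** — overrepresentation of user-supplied
  gene sets (GMT collections) in a signature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .compare import bh_adjust
from .dataset import ExpressionDataset, Signature
from .io import intersect_on_common_genes
from .svm import train_linear_svm

__all__ = [
    "ConfusionCounts",
    "consistency_score",
    "cross_study_predict",
    "accuracy",
    "mcc",
    "study_odds_ratio",
    "random_effects_pool",
    "forest_table",
    "hypergeometric_enrichment",
    "EnrichmentResult",
]

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


# ---------------------------------------------------------------------------
# consistency score
# ---------------------------------------------------------------------------


def consistency_score(signatures: Sequence[Signature | Iterable[str]]) -> int:
    """Total pairwise agreement among >=2 signatures.

    ``CS = sum_g C(m_g, 2)`` with ``m_g`` the number of signatures
    containing gene g.  Nine identical 100-gene signatures give
    ``100 * C(9,2) = 3600``; pairwise-disjoint signatures give 0.
    """
    if len(signatures) < 2:
        raise ValueError("consistency score needs >=2 signatures")
    counts: dict[str, int] = {}
    for sig in signatures:
        for g in set(sig):
            counts[g] = counts.get(g, 0) + 1
    return sum(math.comb(m, 2) for m in counts.values())


# ---------------------------------------------------------------------------
# cross-study prediction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with case as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def correct(self) -> int:
        return self.tp + self.tn

    @property
    def incorrect(self) -> int:
        return self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


def accuracy(counts: ConfusionCounts) -> float:
    """ACC = (TP + TN) / total."""
    if counts.total == 0:
        raise ValueError("empty confusion table")
    return counts.correct / counts.total


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is zero.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); a zero
    marginal (all predictions or all truths on one side) is read as "no
    better than random" and returns 0.
    """
    if counts.total == 0:
        raise ValueError("empty confusion table")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def _tune_C(
    ds: ExpressionDataset, C_grid: Sequence[float], cv_seed: int, n_folds: int = 5
) -> float:
    """Pick C from the grid by stratified CV accuracy (ties: smaller C)."""
    y = ds.label_array()
    n_folds = min(n_folds, int(np.bincount(y).min()))
    if n_folds < 2:
        return sorted(C_grid)[len(C_grid) // 2]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=cv_seed)
    samples = np.array(ds.sample_ids)
    best_C, best_acc = None, -1.0
    for C in sorted(C_grid):
        accs = []
        for tr, te in skf.split(samples, y):
            model = train_linear_svm(ds.subset_samples(list(samples[tr])), C=C)
            test = ds.subset_samples(list(samples[te]))
            accs.append(float((model.predict(test) == test.label_array()).mean()))
        mean_acc = float(np.mean(accs))
        if mean_acc > best_acc:
            best_C, best_acc = C, mean_acc
    return float(best_C)


def cross_study_predict(
    signature: Signature | Iterable[str],
    train_ds: ExpressionDataset,
    test_ds: ExpressionDataset,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    cv_seed: int = 0,
) -> ConfusionCounts:
    """Train on one study, predict another, report confusion counts.

    The classifier uses only the signature genes present in both studies
    (an error if that intersection is empty); C is selected by stratified
    five-fold CV on the training study alone, and per-gene standardization
    comes from the training study only.
    """
    genes = sorted(set(signature) & set(train_ds.gene_ids) & set(test_ds.gene_ids))
    if not genes:
        raise ValueError("signature shares no genes with both studies")
    train_sub, test_sub = intersect_on_common_genes(
        [train_ds.subset_genes(genes), test_ds.subset_genes(genes)]
    )
    C = _tune_C(train_sub, C_grid, cv_seed)
    model = train_linear_svm(train_sub, C=C)
    pred = model.predict(test_sub)
    truth = test_sub.label_array()
    return ConfusionCounts(
        tp=int(((pred == 1) & (truth == 1)).sum()),
        tn=int(((pred == 0) & (truth == 0)).sum()),
        fp=int(((pred == 1) & (truth == 0)).sum()),
        fn=int(((pred == 0) & (truth == 1)).sum()),
    )


# ---------------------------------------------------------------------------
# odds ratios and random-effects pooling
# ---------------------------------------------------------------------------


def study_odds_ratio(
    counts_m1: tuple[int, int], counts_m2: tuple[int, int]
) -> dict[str, float]:
    """Odds ratio of correct classification, method 1 vs method 2.

    Inputs are (correct, incorrect) totals for each method on the same
    test samples.  A zero cell triggers the Haldane-Anscombe +0.5
    continuity correction on all four cells.  Returns the OR, its log, the
    log-OR standard error and the 95% CI.
    """
    c1, i1 = counts_m1
    c2, i2 = counts_m2
    if c1 + i1 == 0 or c2 + i2 == 0:
        raise ValueError("each method needs a non-empty correct/incorrect total")
    cells = [float(v) for v in (c1, i1, c2, i2)]
    if min(cells) == 0:
        cells = [v + 0.5 for v in cells]
    c1f, i1f, c2f, i2f = cells
    log_or = math.log((c1f * i2f) / (i1f * c2f))
    se = math.sqrt(1 / c1f + 1 / i1f + 1 / c2f + 1 / i2f)
    return {
        "or": math.exp(log_or),
        "log_or": log_or,
        "se": se,
        "ci_low": math.exp(log_or - 1.96 * se),
        "ci_high": math.exp(log_or + 1.96 * se),
    }


def random_effects_pool(effect_rows: Sequence[Mapping[str, float]]) -> dict[str, float]:
    """DerSimonian-Laird random-effects pooling of per-study log-ORs.

    Computes Cochran's Q under fixed-effect weights ``1/SE^2``, the
    between-study variance ``tau2 = max(0, (Q - df) / C)``, then pools with
    inverse-variance weights ``1/(SE^2 + tau2)``.  Returns the pooled OR,
    95% CI, tau2 and Q.
    """
    if len(effect_rows) < 2:
        raise ValueError("random-effects pooling needs >=2 studies")
    y = np.array([r["log_or"] for r in effect_rows], dtype=float)
    v = np.array([r["se"] for r in effect_rows], dtype=float) ** 2
    w_fixed = 1.0 / v
    y_fixed = float((w_fixed * y).sum() / w_fixed.sum())
    q = float((w_fixed * (y - y_fixed) ** 2).sum())
    df = len(y) - 1
    c = float(w_fixed.sum() - (w_fixed**2).sum() / w_fixed.sum())
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    w = 1.0 / (v + tau2)
    pooled = float((w * y).sum() / w.sum())
    se = math.sqrt(1.0 / w.sum())
    return {
        "or": math.exp(pooled),
        "log_or": pooled,
        "se": se,
        "ci_low": math.exp(pooled - 1.96 * se),
        "ci_high": math.exp(pooled + 1.96 * se),
        "tau2": tau2,
        "q": q,
    }


def forest_table(
    method_a_results: Sequence[tuple[int, int]],
    method_b_results: Sequence[tuple[int, int]],
    study_ids: Sequence[str],
) -> pd.DataFrame:
    """Per-study OR rows plus a pooled random-effects row.

    ``method_*_results`` are (correct, incorrect) totals per study, in the
    order of ``study_ids``.  Weights are the normalized random-effects
    weights ``1/(SE^2 + tau2)``; the pooled row carries weight 1 and the
    table's ``attrs`` record tau2 and Q.
    """
    if not (len(method_a_results) == len(method_b_results) == len(study_ids)):
        raise ValueError("method results and study ids must align")
    rows = [study_odds_ratio(a, b) for a, b in zip(method_a_results, method_b_results)]
    pooled = random_effects_pool(rows)
    w = np.array([1.0 / (r["se"] ** 2 + pooled["tau2"]) for r in rows])
    w = w / w.sum()
    table = pd.DataFrame(
        {
            "study": list(study_ids) + ["pooled"],
            "or": [r["or"] for r in rows] + [pooled["or"]],
            "ci_low": [r["ci_low"] for r in rows] + [pooled["ci_low"]],
            "ci_high": [r["ci_high"] for r in rows] + [pooled["ci_high"]],
            "weight": list(w) + [1.0],
        }
    )
    table.attrs["tau2"] = pooled["tau2"]
    table.attrs["q"] = pooled["q"]
    return table


def plot_forest(table: pd.DataFrame, ax=None, title: str = ""):
    """Minimal forest plot of a :func:`forest_table` result."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 0.5 * len(table) + 1))
    ys = np.arange(len(table))[::-1]
    for y, (_, row) in zip(ys, table.iterrows()):
        pooled = row["study"] == "pooled"
        ax.plot([row["ci_low"], row["ci_high"]], [y, y], color="k", lw=1)
        ax.scatter(
            [row["or"]],
            [y],
            s=200 * row["weight"] if not pooled else 80,
            marker="s" if not pooled else "D",
            color="tab:blue" if not pooled else "tab:red",
        )
    ax.axvline(1.0, color="grey", ls="--", lw=1)
    ax.set_yticks(ys)
    ax.set_yticklabels(table["study"])
    ax.set_xlabel("odds ratio (log scale)")
    ax.set_xscale("log")
    if title:
        ax.set_title(title)
    return ax


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric overrepresentation of one gene set in a signature."""

    name: str
    overlap: int
    set_size: int
    signature_size: int
    universe_size: int
    p_value: float
    q_value: float
    significant: bool


def hypergeometric_enrichment(
    signature: Signature | Iterable[str],
    gene_set_collection: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric overrepresentation test per gene set.

    Each gene set is intersected with the universe; the p-value is
    ``P(X >= k)`` for ``k`` overlap genes out of a signature of size n,
    set of size K, universe of size N.  Results are sorted by ascending p;
    sets with raw ``p < alpha`` are flagged and a BH-adjusted column is
    included for transparency.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty gene universe")
    sig = set(signature)
    if not sig <= universe_set:
        raise ValueError("signature must be a subset of the universe")
    names, ps, raw = [], [], []
    n, big_n = len(sig), len(universe_set)
    for name, members in gene_set_collection.items():
        members_in = set(members) & universe_set
        k = len(sig & members_in)
        big_k = len(members_in)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n)) if big_k else 1.0
        names.append(name)
        ps.append(min(p, 1.0))
        raw.append((k, big_k))
    qs = bh_adjust(ps) if ps else np.array([])
    results = [
        EnrichmentResult(
            name=name,
            overlap=k,
            set_size=big_k,
            signature_size=n,
            universe_size=big_n,
            p_value=p,
            q_value=float(q),
            significant=p < alpha,
        )
        for name, (k, big_k), p, q in zip(names, raw, ps, qs)
    ]
    return sorted(results, key=lambda r: (r.p_value, r.name))
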