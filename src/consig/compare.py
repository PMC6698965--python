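"""Baseline selectors: BH-corrected Welch t-test and SAM top-k signatures.

Both methods score every gene for case/control differential expression and
take the ``k`` most extreme genes as a signature — the conventional
filter-based procedure the consensus selector is benchmarked against.

The SAM statistic is the moderated t-like quantity

    d_i = (mean_case_i - mean_control_i) / (s_i + s0)

where ``s_i`` is the pooled two-sample standard error of the mean
difference and the fudge factor ``s0`` damps the inflated d-values of
low-variance genes.  ``s0`` is chosen as a fixed percentile (default: the
median) of the ``s_i`` distribution.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataset import CASE, CONTROL, ExpressionDataset, Signature

logger = logging.getLogger(__name__)

__all__ = [
    "ttest_per_gene",
    "bh_adjust",
    "pooled_standard_error",
    "sam_statistic",
    "choose_s0",
    "top_k_signature",
    "select_ttest_topk",
    "select_sam_topk",
]


def _split_cohorts(ds: ExpressionDataset) -> tuple[np.ndarray, np.ndarray]:
    x = ds.matrix.to_numpy(dtype=float)
    y = ds.label_array()
    if (y == CASE).sum() < 2 or (y == CONTROL).sum() < 2:
        raise ValueError("each cohort needs >=2 samples for per-gene statistics")
    return x[:, y == CASE], x[:, y == CONTROL]


def ttest_per_gene(ds: ExpressionDataset) -> pd.DataFrame:
    """Welch two-sample t-test per gene.

    Returns a gene-indexed table with columns ``statistic``, ``p_value``,
    ``q_value`` (BH) and ``rank`` (1 = most significant).  Genes with zero
    variance in both cohorts get t = 0, p = 1 by convention (logged).
    """
    cases, controls = _split_cohorts(ds)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(cases, controls, axis=1, equal_var=False)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        logger.info("ttest_per_gene: %d zero-variance gene(s) set to p=1", degenerate.sum())
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate, 1.0, p)
    q = bh_adjust(p)
    table = pd.DataFrame(
        {"statistic": t, "p_value": p, "q_value": q}, index=ds.matrix.index
    )
    order = sorted(table.index, key=lambda g: (table.at[g, "q_value"], -abs(table.at[g, "statistic"]), g))
    table["rank"] = pd.Series({g: i + 1 for i, g in enumerate(order)})
    return table


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pooled_standard_error(ds: ExpressionDataset) -> np.ndarray:
    """Pooled two-sample standard error of the mean difference, per gene."""
    cases, controls = _split_cohorts(ds)
    n1, n2 = cases.shape[1], controls.shape[1]
    ss = cases.var(axis=1, ddof=1) * (n1 - 1) + controls.var(axis=1, ddof=1) * (n2 - 1)
    return np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))


def sam_statistic(ds: ExpressionDataset, s0: float = 0.0) -> pd.DataFrame:
    """SAM d statistic per gene; ranked by \\|d\\| descending.

    With ``s0 = 0`` the statistic reduces to the pooled-variance t
    statistic; as ``s0`` grows all d-values shrink toward 0.
    """
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    cases, controls = _split_cohorts(ds)
    diff = cases.mean(axis=1) - controls.mean(axis=1)
    s = pooled_standard_error(ds)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = diff / (s + s0)
    d = np.where(np.isfinite(d), d, 0.0)
    table = pd.DataFrame({"statistic": d}, index=ds.matrix.index)
    order = sorted(table.index, key=lambda g: (-abs(table.at[g, "statistic"]), g))
    table["rank"] = pd.Series({g: i + 1 for i, g in enumerate(order)})
    return table


def choose_s0(ds: ExpressionDataset, percentile: float = 50.0) -> float:
    """Fudge factor: a fixed percentile of the per-gene pooled SE values."""
    if not 0 <= percentile <= 100:
        raise ValueError("percentile must be in [0, 100]")
    return float(np.percentile(pooled_standard_error(ds), percentile))


def top_k_signature(table: pd.DataFrame, k: int = 100, method_name: str = "") -> Signature:
    """The ``k`` most extreme genes of a statistic table.

    Tables with a ``q_value`` column (t-test) are ordered by ascending q,
    ties by \\|t\\|; otherwise by \\|statistic\\| descending.  Remaining ties
    break lexicographically, so selection is deterministic.
    """
    if k > len(table):
        raise ValueError(f"k={k} exceeds the {len(table)} genes in the table")
    if "q_value" in table.columns:
        key = lambda g: (table.at[g, "q_value"], -abs(table.at[g, "statistic"]), g)
    else:
        key = lambda g: (-abs(table.at[g, "statistic"]), g)
    chosen = sorted(table.index, key=key)[:k]
    return Signature(chosen, provenance={"method": method_name or "top-k", "k": k})


def select_ttest_topk(ds: ExpressionDataset, k: int = 100) -> Signature:
    """BH-corrected Welch t-test top-k signature for one study."""
    sig = top_k_signature(ttest_per_gene(ds), k=k, method_name="ttest-bh")
    return Signature(sig.genes, {**sig.provenance, "study": ds.study_id})


def select_sam_topk(ds: ExpressionDataset, k: int = 100, s0: float | None = None) -> Signature:
    """SAM top-k signature for one study (s0 defaults to the median SE)."""
    if s0 is None:
        s0 = choose_s0(ds)
    sig = top_k_signature(sam_statistic(ds, s0=s0), k=k, method_name="sam")
    return Signature(sig.genes, {**sig.provenance, "study": ds.study_id, "s0": s0})
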