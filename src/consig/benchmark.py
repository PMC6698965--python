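"""Desk-scale multi-study benchmark: consensus vs baseline selectors.

Runs the full pipeline on a synthetic multi-study compendium: per study, a
consensus SVM-RFE signature plus t-test/BH and SAM top-k signatures; then
the cross-study evaluation — consistency scores, planted-signature
recovery of the majority-vote signature, and random-effects pooled odds
ratios of correct cross-study classification (consensus vs each baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .compare import select_sam_topk, select_ttest_topk
from .consensus import ConsensusRFE, majority_signature
from .dataset import ExpressionDataset, Signature
from .evaluate import (
    consistency_score,
    cross_study_predict,
    random_effects_pool,
    study_odds_ratio,
)
from .simulate import SimulationConfig, simulate_multistudy

__all__ = ["BenchmarkResult", "run_benchmark", "signature_recovery"]


def signature_recovery(signature: Signature, truth: frozenset[str]) -> tuple[float, float]:
    """(recall of planted genes, fraction of signature members not planted)."""
    sig = set(signature)
    if not sig:
        return 0.0, 0.0
    hits = len(sig & truth)
    return hits / len(truth), (len(sig) - hits) / len(sig)


@dataclass
class BenchmarkResult:
    """Everything the cross-study benchmark computes."""

    config: SimulationConfig
    truth: frozenset[str]
    consensus_signatures: list[Signature]
    ttest_signatures: list[Signature]
    sam_signatures: list[Signature]
    majority: Signature
    cs: dict[str, int]
    recall: float
    false_member_rate: float
    prediction: pd.DataFrame | None = None
    pooled_or: dict[str, dict[str, float]] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"benchmark seed={self.config.seed} effect={self.config.effect_size}",
            f"consensus sizes: {[len(s) for s in self.consensus_signatures]}",
            f"CS: consensus={self.cs['consensus']} ttest={self.cs['ttest']} sam={self.cs['sam']}",
            f"majority signature: {len(self.majority)} genes, recall={self.recall:.2f}, "
            f"false member rate={self.false_member_rate:.2f}",
        ]
        for name, pooled in self.pooled_or.items():
            lines.append(
                f"pooled OR consensus vs {name}: {pooled['or']:.3f} "
                f"[{pooled['ci_low']:.3f}, {pooled['ci_high']:.3f}]"
            )
        return "\n".join(lines)


def _pooled_counts(
    signatures: list[Signature], datasets: list[ExpressionDataset], cv_seed: int
) -> list[tuple[int, int]]:
    """Per train-study (correct, incorrect) totals over the other studies."""
    rows = []
    for i, train in enumerate(datasets):
        correct = incorrect = 0
        for j, test in enumerate(datasets):
            if i == j:
                continue
            counts = cross_study_predict(signatures[i], train, test, cv_seed=cv_seed)
            correct += counts.correct
            incorrect += counts.incorrect
        rows.append((correct, incorrect))
    return rows


def run_benchmark(
    cfg: SimulationConfig,
    n_splits: int = 100,
    n_groups: int = 5,
    k_baseline: int = 100,
    min_genes: int = 5,
    with_prediction: bool = True,
) -> BenchmarkResult:
    """Run the full multi-study benchmark under one master seed (cfg.seed)."""
    studies = simulate_multistudy(cfg)
    truth = studies[0][1].signature
    datasets = [ds for ds, _ in studies]

    cons_sigs, t_sigs, sam_sigs = [], [], []
    for ds in datasets:
        res = ConsensusRFE(
            ds,
            n_splits=n_splits,
            n_groups=n_groups,
            min_genes=min_genes,
            master_seed=cfg.seed,
        ).fit()
        cons_sigs.append(res.signature)
        t_sigs.append(select_ttest_topk(ds, k=k_baseline))
        sam_sigs.append(select_sam_topk(ds, k=k_baseline))

    majority = majority_signature(cons_sigs, fraction=0.5)
    recall, false_rate = signature_recovery(majority, truth)
    cs = {
        "consensus": consistency_score(cons_sigs),
        "ttest": consistency_score(t_sigs),
        "sam": consistency_score(sam_sigs),
    }

    result = BenchmarkResult(
        config=cfg,
        truth=truth,
        consensus_signatures=cons_sigs,
        ttest_signatures=t_sigs,
        sam_signatures=sam_sigs,
        majority=majority,
        cs=cs,
        recall=recall,
        false_member_rate=false_rate,
    )
    if not with_prediction:
        return result

    counts = {
        "consensus": _pooled_counts(cons_sigs, datasets, cfg.seed),
        "ttest": _pooled_counts(t_sigs, datasets, cfg.seed),
        "sam": _pooled_counts(sam_sigs, datasets, cfg.seed),
    }
    pred_rows = []
    for name, rows in counts.items():
        for ds, (c, i) in zip(datasets, rows):
            total = c + i
            pred_rows.append(
                {
                    "method": name,
                    "train_study": ds.study_id,
                    "correct": c,
                    "incorrect": i,
                    "acc": c / total,
                }
            )
    result.prediction = pd.DataFrame(pred_rows)
    for name in ("ttest", "sam"):
        rows = [
            study_odds_ratio(a, b) for a, b in zip(counts["consensus"], counts[name])
        ]
        result.pooled_or[name] = random_effects_pool(rows)
        result.pooled_or[name]["rows"] = rows
    return result
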