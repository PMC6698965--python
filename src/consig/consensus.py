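"""Repeated-random-sampling consensus SVM-RFE.

The selector enhances the reproducibility of SVM-RFE signatures by
requiring agreement across many random training/test partitions before a
gene is eliminated:

1.  The study is split into ``n_splits`` unique stratified half/half
    training-test partitions, which are randomly bundled into ``n_groups``
    sampling groups.
2.  Within a group, each elimination round trains one linear SVM per
    split and applies three sequential consensus rules:

    * **alpha** — per split, the largest low-ranked suffix (at most half
      of the surviving genes) whose collective contribution (sum of
      squared SVM weights) stays strictly below that of the remaining
      top-ranked genes becomes the split's elimination candidates;
    * **beta** — candidates must also have sat in the bottom half of the
      split's ranking in the *previous* round, so only genes that are
      consistently low-ranked survive as candidates;
    * **gamma** — genes proposed as candidates by more than 90% of the
      group's splits are eliminated.

3.  After each round the surviving set's mean test accuracy over the
    group's test halves is recorded; the group signature is the surviving
    set at the round of maximum mean accuracy (ties prefer fewer genes,
    then the earlier round).
4.  The study signature is the intersection of the group signatures; a
    cross-study signature keeps genes selected by at least half of the
    studies.

Everything is deterministic given one master seed.

The faithful full-scale setting is 1000 splits in 10 groups of 100; the
package defaults are scaled for desk use (100 splits, 5 groups) and both
are plain parameters of :class:`ConsensusRFE`.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset, Signature
from .svm import GeneRanking

__all__ = [
    "TrainTestSplit",
    "SamplingGroup",
    "RoundRecord",
    "EliminationTrace",
    "make_splits",
    "group_splits",
    "alpha_candidates",
    "beta_filter",
    "gamma_eliminate",
    "run_group",
    "intersect_groups",
    "majority_signature",
    "ConsensusRFE",
    "ConsensusRFEResults",
]


# ---------------------------------------------------------------------------
# splits and groups
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainTestSplit:
    """One stratified half/half random partition of a study's samples.

    Per cohort the training half holds floor(n/2) samples; the remainder
    (including the odd sample) goes to the test half.
    """

    index: int
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]


@dataclass(frozen=True)
class SamplingGroup:
    """A bundle of unique splits analysed jointly by the consensus rules."""

    group_index: int
    splits: tuple[TrainTestSplit, ...]

    @property
    def n_splits(self) -> int:
        return len(self.splits)


def make_splits(
    ds: ExpressionDataset, n_splits: int = 1000, master_seed: int = 0
) -> list[TrainTestSplit]:
    """Draw ``n_splits`` distinct stratified half/half partitions.

    Training halves take floor(n/2) samples per cohort.  Distinctness is
    enforced on the training set; if more distinct partitions are
    requested than exist, the error names the maximum.
    """
    cases = sorted(ds.case_ids)
    controls = sorted(ds.control_ids)
    if len(cases) < 2 or len(controls) < 2:
        raise ValueError("each cohort needs >=2 samples to split")
    k_case, k_ctrl = len(cases) // 2, len(controls) // 2
    max_splits = math.comb(len(cases), k_case) * math.comb(len(controls), k_ctrl)
    if n_splits > max_splits:
        raise ValueError(
            f"requested {n_splits} distinct splits but only {max_splits} "
            f"stratified half/half partitions exist"
        )
    rng = np.random.default_rng(np.random.SeedSequence([master_seed, 101]))
    seen: set[frozenset[str]] = set()
    splits: list[TrainTestSplit] = []
    attempts = 0
    max_attempts = 1000 * n_splits
    while len(splits) < n_splits:
        attempts += 1
        if attempts > max_attempts:  # pragma: no cover - safety valve
            raise RuntimeError("could not draw enough distinct splits")
        train = sorted(rng.choice(cases, size=k_case, replace=False)) + sorted(
            rng.choice(controls, size=k_ctrl, replace=False)
        )
        key = frozenset(train)
        if key in seen:
            continue
        seen.add(key)
        test = tuple(s for s in cases + controls if s not in key)
        splits.append(TrainTestSplit(index=len(splits), train_ids=tuple(train), test_ids=test))
    return splits


def group_splits(
    splits: Sequence[TrainTestSplit], n_groups: int = 10, master_seed: int = 0
) -> list[SamplingGroup]:
    """Randomly partition the splits into ``n_groups`` balanced groups."""
    if len(splits) % n_groups != 0:
        raise ValueError(f"{len(splits)} splits not divisible into {n_groups} groups")
    per_group = len(splits) // n_groups
    rng = np.random.default_rng(np.random.SeedSequence([master_seed, 202]))
    order = rng.permutation(len(splits))
    return [
        SamplingGroup(
            group_index=g + 1,
            splits=tuple(splits[i] for i in order[g * per_group : (g + 1) * per_group]),
        )
        for g in range(n_groups)
    ]


# ---------------------------------------------------------------------------
# the three consensus rules
# ---------------------------------------------------------------------------


def alpha_candidates(ranking: GeneRanking) -> frozenset[str]:
    """Rule alpha: low-ranked genes whose collective contribution stays
    strictly below the top-ranked genes'.

    Walking the ranking from the bottom, take the largest suffix B with
    ``|B| <= floor(n/2)`` and ``sum(c_i for i in B) < sum(c_i for i not in
    B)``, where ``c_i = w_i^2``.  May be empty when even the single
    lowest-criterion gene already violates the condition.
    """
    n = ranking.n
    if n < 2:
        return frozenset()
    total = sum(ranking.criteria.values())
    cap = n // 2
    suffix_sum = 0.0
    best_k = 0
    # ranking.order is descending; walk from the tail upwards
    for k in range(1, cap + 1):
        suffix_sum += ranking.criteria[ranking.order[n - k]]
        if suffix_sum < total - suffix_sum:
            best_k = k
        else:
            break
    return frozenset(ranking.order[n - best_k :]) if best_k else frozenset()


def beta_filter(
    candidates: frozenset[str],
    current_ranking: GeneRanking,
    previous_ranking: GeneRanking | None,
) -> frozenset[str]:
    """Rule beta: keep candidates that were also bottom-half in the
    previous round's ranking (first round: all candidates pass)."""
    if previous_ranking is None:
        return candidates
    return candidates & previous_ranking.bottom_half()


def gamma_eliminate(
    candidate_sets: Sequence[frozenset[str]], agreement: float = 0.90
) -> frozenset[str]:
    """Rule gamma: eliminate genes appearing in strictly more than
    ``agreement`` of the splits' candidate sets.

    When no gene crosses the threshold, falls back to the genes at the
    maximum observed candidate frequency so that elimination can always
    proceed (ties are eliminated jointly).  Returns the empty set only if
    every candidate set is empty.
    """
    counts: Counter[str] = Counter()
    for cs in candidate_sets:
        counts.update(cs)
    if not counts:
        return frozenset()
    threshold = agreement * len(candidate_sets)
    eliminated = {g for g, c in counts.items() if c > threshold}
    if not eliminated:
        max_freq = max(counts.values())
        eliminated = {g for g, c in counts.items() if c == max_freq}
    return frozenset(eliminated)


# ---------------------------------------------------------------------------
# group-level elimination
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RoundRecord:
    """Audit record of one elimination round within a sampling group."""

    round_index: int
    surviving: tuple[str, ...]
    mean_test_accuracy: float
    eliminated: tuple[str, ...]
    candidate_counts: Mapping[str, int] = field(default_factory=dict, repr=False)


@dataclass(frozen=True)
class EliminationTrace:
    """Per-round audit trail of one sampling group's consensus RFE."""

    group_index: int
    rounds: tuple[RoundRecord, ...]

    def to_frame(self) -> pd.DataFrame:
        """Tabular round log (one row per round)."""
        return pd.DataFrame(
            {
                "group": self.group_index,
                "round": [r.round_index for r in self.rounds],
                "n_genes": [len(r.surviving) for r in self.rounds],
                "mean_test_accuracy": [r.mean_test_accuracy for r in self.rounds],
                "n_eliminated": [len(r.eliminated) for r in self.rounds],
                "eliminated": [";".join(r.eliminated) for r in self.rounds],
            }
        )

    def best_round(self) -> RoundRecord:
        """Round of maximum mean accuracy; ties prefer fewer genes, then
        the earlier round."""
        return min(
            self.rounds,
            key=lambda r: (-r.mean_test_accuracy, len(r.surviving), r.round_index),
        )


def run_group(
    ds: ExpressionDataset,
    group: SamplingGroup,
    C: float = 1.0,
    min_genes: int = 5,
    agreement: float = 0.90,
) -> tuple[EliminationTrace, Signature]:
    """Run consensus RFE for one sampling group.

    Each round trains one SVM per split on the surviving genes, applies the
    alpha/beta/gamma rules, and records the surviving set's mean test
    accuracy over the group's test halves.  Rounds continue until
    ``min_genes`` survive or elimination stalls; if the gamma rule yields
    nothing (all candidate sets empty) the gene with the smallest mean
    squared weight across splits is eliminated so the procedure always
    terminates.  The group signature is the surviving set of
    :meth:`EliminationTrace.best_round`.

    The inner loop is a vectorized equivalent of the public operations
    (:func:`~consig.svm.train_linear_svm` + :func:`~consig.svm.rank_genes`
    + alpha/beta/gamma); agreement between the two routes is asserted in
    the test suite.
    """
    from sklearn.svm import SVC

    x_all = ds.matrix.to_numpy(dtype=float)  # genes x samples
    gene_names = np.asarray(ds.gene_ids)
    sample_pos = {s: i for i, s in enumerate(ds.sample_ids)}
    y = ds.label_array()
    tr_idx = [np.array([sample_pos[s] for s in sp.train_ids]) for sp in group.splits]
    te_idx = [np.array([sample_pos[s] for s in sp.test_ids]) for sp in group.splits]
    n_splits = group.n_splits
    n_total = len(gene_names)

    surv = np.argsort(gene_names)  # gene positions, lexicographic order
    prev_bottom: list[np.ndarray | None] = [None] * n_splits  # bool over all genes
    rounds: list[RoundRecord] = []
    round_index = 0
    while True:
        p = len(surv)
        xs = x_all[surv]  # p x samples
        cap = p // 2
        accs = np.empty(n_splits)
        cand_count = np.zeros(p, dtype=int)
        crit_sum = np.zeros(p)
        new_bottom: list[np.ndarray] = []
        for k in range(n_splits):
            xtr = xs[:, tr_idx[k]].T
            mu = xtr.mean(axis=0)
            sd = xtr.std(axis=0)
            sd[sd == 0] = 1.0
            ztr = (xtr - mu) / sd
            clf = SVC(kernel="precomputed", C=C)
            clf.fit(ztr @ ztr.T, y[tr_idx[k]])
            w = (clf.dual_coef_ @ ztr[clf.support_]).ravel()
            b = float(clf.intercept_[0])
            zte = (xs[:, te_idx[k]].T - mu) / sd
            pred = (zte @ w + b > 0).astype(int)
            accs[k] = (pred == y[te_idx[k]]).mean()

            crit = w * w
            crit_sum += crit
            # descending criterion; surv is lexicographic so a stable sort
            # breaks ties lexicographically, matching rank_genes()
            desc = np.argsort(-crit, kind="stable")
            asc = desc[::-1]
            # alpha: largest low-criterion suffix (<= floor(p/2)) whose sum
            # stays strictly below the complement's sum
            cum = np.cumsum(crit[asc][:cap])
            total = float(crit.sum())
            ok = cum < (total - cum)
            best_k = int(ok.sum()) if ok.all() else int(np.argmin(ok))
            cand = np.zeros(p, dtype=bool)
            cand[asc[:best_k]] = True
            # beta: must have been bottom-half in this split's previous round
            if prev_bottom[k] is not None:
                cand &= prev_bottom[k][surv]
            cand_count += cand
            bottom = np.zeros(n_total, dtype=bool)
            bottom[surv[asc[:cap]]] = True
            new_bottom.append(bottom)
        mean_acc = float(accs.mean())
        surviving_names = tuple(str(g) for g in gene_names[surv])

        if p <= min_genes:
            rounds.append(RoundRecord(round_index, surviving_names, mean_acc, eliminated=()))
            break

        # gamma: strictly more than `agreement` of the splits
        elim = cand_count > agreement * n_splits
        if not elim.any():
            if cand_count.max() > 0:
                elim = cand_count == cand_count.max()
            else:
                # stall guard: lowest mean squared weight (ties: lexicographic)
                elim = np.zeros(p, dtype=bool)
                elim[int(np.argmin(crit_sum))] = True
        if p - int(elim.sum()) < min_genes:
            keep = np.argsort(-crit_sum, kind="stable")[:min_genes]
            elim = np.ones(p, dtype=bool)
            elim[keep] = False
            if not elim.any():
                rounds.append(
                    RoundRecord(round_index, surviving_names, mean_acc, eliminated=())
                )
                break

        elim_names = tuple(sorted(str(g) for g in gene_names[surv[elim]]))
        counts_by_name = dict(zip(surviving_names, cand_count))
        rounds.append(
            RoundRecord(
                round_index,
                surviving_names,
                mean_acc,
                eliminated=elim_names,
                candidate_counts={g: int(counts_by_name[g]) for g in elim_names},
            )
        )
        surv = surv[~elim]
        prev_bottom = new_bottom
        round_index += 1

    trace = EliminationTrace(group_index=group.group_index, rounds=tuple(rounds))
    best = trace.best_round()
    signature = Signature(
        best.surviving,
        provenance={
            "method": "consensus-svm-rfe",
            "study": ds.study_id,
            "group": group.group_index,
            "round": best.round_index,
            "mean_test_accuracy": best.mean_test_accuracy,
        },
    )
    return trace, signature


# ---------------------------------------------------------------------------
# signature combination
# ---------------------------------------------------------------------------


def intersect_groups(group_signatures: Sequence[Signature]) -> Signature:
    """Genes identified simultaneously by all sampling groups."""
    if not group_signatures:
        raise ValueError("need at least one group signature")
    common = set(group_signatures[0].genes)
    for sig in group_signatures[1:]:
        common &= sig.gene_set
    provenance = {
        "method": "consensus-svm-rfe",
        "study": group_signatures[0].provenance.get("study"),
        "groups": [s.provenance.get("group") for s in group_signatures],
        "empty": len(common) == 0,
    }
    return Signature(common, provenance)


def majority_signature(
    study_signatures: Sequence[Signature], fraction: float = 0.5
) -> Signature:
    """Genes selected by at least ``fraction`` of the studies.

    The threshold is ``ceil(fraction * n_studies)`` votes; provenance
    records the per-gene vote counts.
    """
    if len(study_signatures) < 2:
        raise ValueError("majority vote needs >=2 study signatures")
    votes: Counter[str] = Counter()
    for sig in study_signatures:
        votes.update(sig.genes)
    needed = math.ceil(fraction * len(study_signatures))
    chosen = {g for g, v in votes.items() if v >= needed}
    return Signature(
        chosen,
        provenance={
            "method": "majority-vote",
            "n_studies": len(study_signatures),
            "votes_needed": needed,
            "votes": {g: votes[g] for g in sorted(chosen)},
        },
    )


# ---------------------------------------------------------------------------
# model / results facade
# ---------------------------------------------------------------------------


class ConsensusRFE:
    """Consensus SVM-RFE signature selector for one two-cohort study.

    Parameters
    ----------
    dataset
        The study to analyse (preprocessed, log scale).
    n_splits, n_groups
        Number of unique stratified half/half partitions and the number of
        sampling groups they are bundled into.  The faithful full-scale
        setting is 1000/10; defaults are desk-scale (100/5).
    C
        Soft-margin penalty of every SVM trained inside the loop.
    agreement
        The gamma rule's threshold: a gene is eliminated when it is an
        elimination candidate in strictly more than this fraction of a
        group's splits.
    min_genes
        Floor on the surviving set size.
    master_seed
        Single integer fixing splits, grouping and hence the signature.

    Examples
    --------
    >>> res = ConsensusRFE(ds, master_seed=7).fit()   # doctest: +SKIP
    >>> res.signature.genes                            # doctest: +SKIP
    """

    def __init__(
        self,
        dataset: ExpressionDataset,
        n_splits: int = 100,
        n_groups: int = 5,
        C: float = 1.0,
        agreement: float = 0.90,
        min_genes: int = 5,
        master_seed: int = 0,
    ):
        if n_splits % n_groups != 0:
            raise ValueError("n_splits must be divisible by n_groups")
        self.dataset = dataset
        self.n_splits = n_splits
        self.n_groups = n_groups
        self.C = C
        self.agreement = agreement
        self.min_genes = min_genes
        self.master_seed = master_seed

    @classmethod
    def from_files(
        cls, matrix_path, metadata_path, preprocess: bool = False, **kwargs
    ) -> "ConsensusRFE":
        """Build the selector straight from a matrix/metadata file pair."""
        from .io import log_and_normalize, read_expression_matrix

        ds = read_expression_matrix(matrix_path, metadata_path)
        if preprocess:
            ds = log_and_normalize(ds)
        return cls(ds, **kwargs)

    def fit(self) -> "ConsensusRFEResults":
        """Run the full consensus pipeline and return the results."""
        splits = make_splits(self.dataset, self.n_splits, self.master_seed)
        groups = group_splits(splits, self.n_groups, self.master_seed)
        traces: list[EliminationTrace] = []
        group_sigs: list[Signature] = []
        for group in groups:
            trace, sig = run_group(
                self.dataset,
                group,
                C=self.C,
                min_genes=self.min_genes,
                agreement=self.agreement,
            )
            traces.append(trace)
            group_sigs.append(sig)
        signature = intersect_groups(group_sigs)
        signature = Signature(
            signature.genes,
            provenance={**signature.provenance, "master_seed": self.master_seed},
        )
        return ConsensusRFEResults(self, signature, tuple(group_sigs), tuple(traces))


@dataclass(frozen=True)
class ConsensusRFEResults:
    """Results of a fitted :class:`ConsensusRFE`.

    Carries the study signature (intersection over the sampling groups),
    the per-group signatures with the round and accuracy at which each was
    chosen, and the complete elimination traces.
    """

    model: ConsensusRFE
    signature: Signature
    group_signatures: tuple[Signature, ...]
    traces: tuple[EliminationTrace, ...]

    def round_log(self) -> pd.DataFrame:
        """All groups' round logs in one table."""
        return pd.concat([t.to_frame() for t in self.traces], ignore_index=True)

    def group_summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": [s.provenance.get("group") for s in self.group_signatures],
                "chosen_round": [s.provenance.get("round") for s in self.group_signatures],
                "n_genes": [len(s) for s in self.group_signatures],
                "mean_test_accuracy": [
                    s.provenance.get("mean_test_accuracy") for s in self.group_signatures
                ],
            }
        )

    def summary(self) -> str:
        """Human-readable fit report."""
        m = self.model
        lines = [
            "Consensus SVM-RFE results",
            "=========================",
            f"study:           {m.dataset.study_id}",
            f"samples:         {m.dataset.n_samples} "
            f"({len(m.dataset.case_ids)} case / {len(m.dataset.control_ids)} control)",
            f"genes:           {m.dataset.n_genes}",
            f"splits/groups:   {m.n_splits} / {m.n_groups}",
            f"C / agreement:   {m.C} / {m.agreement}",
            f"master seed:     {m.master_seed}",
            "",
            self.group_summary().to_string(index=False),
            "",
            f"consensus signature ({len(self.signature)} genes):",
            "  " + (", ".join(self.signature.genes) if len(self.signature) else "<empty>"),
        ]
        return "\n".join(lines)
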