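"""Consensus selector: splits, alpha/beta/gamma rules, group runs, voting."""

import math

import numpy as np
import pytest

from consig.consensus import (
    ConsensusRFE,
    SamplingGroup,
    alpha_candidates,
    beta_filter,
    gamma_eliminate,
    group_splits,
    intersect_groups,
    majority_signature,
    make_splits,
    run_group,
)
from consig.dataset import Signature
from consig.simulate import SimulationConfig, simulate_study
from consig.svm import GeneRanking, rank_genes, train_linear_svm

from conftest import make_dataset


def ranking_from(criteria: dict[str, float]) -> GeneRanking:
    order = tuple(sorted(criteria, key=lambda g: (-criteria[g], g)))
    return GeneRanking(order=order, criteria=criteria)


def two_cohort_dataset(n_case, n_control, n_genes=4, seed=0):
    rng = np.random.default_rng(seed)
    return make_dataset(rng.normal(size=(n_genes, n_case + n_control)), n_case=n_case)


class TestMakeSplits:
    def test_even_cohorts_split_in_half(self):
        ds = two_cohort_dataset(4, 4)
        splits = make_splits(ds, n_splits=4, master_seed=0)
        for sp in splits:
            train_cases = [s for s in sp.train_ids if s in ds.case_ids]
            train_ctrls = [s for s in sp.train_ids if s in ds.control_ids]
            assert len(train_cases) == 2 and len(train_ctrls) == 2
            assert sorted(sp.train_ids + sp.test_ids) == sorted(ds.sample_ids)
            assert not set(sp.train_ids) & set(sp.test_ids)

    def test_odd_cohorts_floor_to_training(self):
        # 34 cases : 31 controls -> train 17+15, test 17+16
        ds = two_cohort_dataset(34, 31, seed=1)
        sp = make_splits(ds, n_splits=3, master_seed=0)[0]
        train_cases = [s for s in sp.train_ids if s in ds.case_ids]
        train_ctrls = [s for s in sp.train_ids if s in ds.control_ids]
        assert (len(train_cases), len(train_ctrls)) == (17, 15)
        test_cases = [s for s in sp.test_ids if s in ds.case_ids]
        test_ctrls = [s for s in sp.test_ids if s in ds.control_ids]
        assert (len(test_cases), len(test_ctrls)) == (17, 16)

    def test_more_splits_than_partitions_errors_with_maximum(self):
        ds = two_cohort_dataset(2, 2)
        # C(2,1) * C(2,1) = 4 distinct partitions exist
        assert math.comb(2, 1) * math.comb(2, 1) == 4
        with pytest.raises(ValueError, match="only 4"):
            make_splits(ds, n_splits=10, master_seed=0)

    def test_splits_are_distinct_and_deterministic(self):
        ds = two_cohort_dataset(6, 6)
        a = make_splits(ds, n_splits=50, master_seed=9)
        b = make_splits(ds, n_splits=50, master_seed=9)
        assert [s.train_ids for s in a] == [s.train_ids for s in b]
        assert len({frozenset(s.train_ids) for s in a}) == 50


class TestGroupSplits:
    def test_balanced_grouping(self):
        ds = two_cohort_dataset(6, 6)
        splits = make_splits(ds, n_splits=20, master_seed=0)
        groups = group_splits(splits, n_groups=4, master_seed=0)
        assert [g.n_splits for g in groups] == [5, 5, 5, 5]
        seen = [s.index for g in groups for s in g.splits]
        assert sorted(seen) == list(range(20))

    def test_indivisible_errors(self):
        ds = two_cohort_dataset(6, 6)
        splits = make_splits(ds, n_splits=10, master_seed=0)
        with pytest.raises(ValueError, match="divisible"):
            group_splits(splits, n_groups=3, master_seed=0)

    def test_same_seed_same_grouping(self):
        ds = two_cohort_dataset(6, 6)
        splits = make_splits(ds, n_splits=20, master_seed=0)
        a = group_splits(splits, 4, master_seed=3)
        b = group_splits(splits, 4, master_seed=3)
        assert [[s.index for s in g.splits] for g in a] == [
            [s.index for s in g.splits] for g in b
        ]


class TestAlphaRule:
    def test_dominant_top_gene_allows_two_candidates(self):
        r = ranking_from({"g1": 9.0, "g2": 1.0, "g3": 1.0, "g4": 1.0})
        # bottom-half cap is 2; the two lowest sum to 2 < 10
        assert alpha_candidates(r) == {"g3", "g4"}

    def test_uniform_criteria_yield_single_lowest(self):
        r = ranking_from({"a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0})
        # suffix of size 2 fails (2 < 2 is false); size 1 passes; the
        # lexicographically last gene holds the lowest rank slot
        assert alpha_candidates(r) == {"d"}

    def test_zero_weight_gene_is_the_candidate(self):
        r = ranking_from({"x": 0.0, "y": 5.0})
        assert alpha_candidates(r) == {"x"}

    def test_may_be_empty_when_lowest_gene_violates(self):
        r = ranking_from({"a": 5.0, "b": 5.0})
        assert alpha_candidates(r) == frozenset()


class TestBetaRule:
    def test_first_round_passes_all(self):
        cur = ranking_from({"a": 3.0, "b": 2.0, "c": 1.0, "d": 0.5})
        assert beta_filter(frozenset({"c", "d"}), cur, None) == {"c", "d"}

    def test_previous_top_half_gene_removed(self):
        prev = ranking_from({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        cur = ranking_from({"a": 4.0, "b": 3.0, "c": 2.0, "d": 1.0})
        # previous bottom half is {a, b}
        assert prev.bottom_half() == {"a", "b"}
        assert beta_filter(frozenset({"b", "c"}), cur, prev) == {"b"}


class TestGammaRule:
    def test_strict_ninety_percent_threshold(self):
        sets_91 = [frozenset({"g"})] * 91 + [frozenset()] * 9
        sets_90 = [frozenset({"g"})] * 90 + [frozenset()] * 10
        assert gamma_eliminate(sets_91, agreement=0.9) == {"g"}
        # exactly 90 of 100 does not exceed the strict threshold; the
        # max-frequency fallback then still returns the gene
        counts_90 = gamma_eliminate(sets_90, agreement=0.9)
        assert "g" in counts_90  # via fallback, not threshold
        # with a competitor above threshold, the 90-count gene is spared
        sets_mixed = [frozenset({"g", "h"})] * 90 + [frozenset({"h"})] * 10
        assert gamma_eliminate(sets_mixed, agreement=0.9) == {"h"}

    def test_unanimous_candidate_eliminated(self):
        assert gamma_eliminate([frozenset({"g"})] * 10) == {"g"}

    def test_fallback_eliminates_tied_max_frequency(self):
        sets = [frozenset({"a"})] * 50 + [frozenset({"b"})] * 50
        assert gamma_eliminate(sets, agreement=0.9) == {"a", "b"}

    def test_all_empty_sets_give_empty_elimination(self):
        assert gamma_eliminate([frozenset()] * 5) == frozenset()


def reference_run_group(ds, group, C=1.0, min_genes=5, agreement=0.9):
    """Slow reference: the public per-split operations composed literally."""
    surviving = sorted(ds.gene_ids)
    prev = {sp.index: None for sp in group.splits}
    rounds = []
    while True:
        sub = ds.subset_genes(surviving)
        accs, rankings, cands = [], {}, []
        for sp in group.splits:
            model = train_linear_svm(sub.subset_samples(list(sp.train_ids)), C=C)
            ranking = rank_genes(model)
            rankings[sp.index] = ranking
            test = sub.subset_samples(list(sp.test_ids))
            accs.append(float((model.predict(test) == test.label_array()).mean()))
            cands.append(beta_filter(alpha_candidates(ranking), ranking, prev[sp.index]))
        mean_acc = float(np.mean(accs))
        if len(surviving) <= min_genes:
            rounds.append((tuple(surviving), mean_acc, ()))
            break
        elim = gamma_eliminate(cands, agreement=agreement)
        if not elim:
            crit = {
                g: float(np.mean([rankings[sp.index].criteria[g] for sp in group.splits]))
                for g in surviving
            }
            elim = frozenset([min(surviving, key=lambda g: (crit[g], g))])
        if len(surviving) - len(elim) < min_genes:
            crit = {
                g: float(np.mean([rankings[sp.index].criteria[g] for sp in group.splits]))
                for g in surviving
            }
            keep = sorted(surviving, key=lambda g: (-crit[g], g))[:min_genes]
            elim = frozenset(set(surviving) - set(keep))
        rounds.append((tuple(surviving), mean_acc, tuple(sorted(elim))))
        surviving = sorted(set(surviving) - elim)
        prev = rankings
    return rounds


class TestRunGroup:
    @pytest.fixture(scope="class")
    def easy_study(self):
        cfg = SimulationConfig(
            n_genes=100,
            n_signal_genes=10,
            n_case=15,
            n_control=15,
            n_studies=2,
            effect_size=2.0,
            effect_attenuation=(1.0, 1.0),
            label_noise=0.0,
            outlier_fraction=0.0,
            noise_sd=1.0,
            seed=5,
        )
        return simulate_study(cfg, 0)

    def test_recovers_most_signal_genes_with_high_accuracy(self, easy_study):
        ds, truth = easy_study
        splits = make_splits(ds, n_splits=20, master_seed=5)
        (group,) = group_splits(splits, n_groups=1, master_seed=5)
        trace, sig = run_group(ds, group, min_genes=5)
        hits = len(set(sig) & truth.signature)
        assert hits >= len(sig) / 2
        assert hits >= 5
        assert trace.best_round().mean_test_accuracy > 0.85

    def test_matches_reference_implementation(self, easy_study):
        ds, _ = easy_study
        small = ds.subset_genes(sorted(ds.gene_ids)[:30])
        splits = make_splits(small, n_splits=6, master_seed=1)
        (group,) = group_splits(splits, n_groups=1, master_seed=1)
        trace, _ = run_group(small, group, min_genes=4)
        ref = reference_run_group(small, group, min_genes=4)
        assert len(trace.rounds) == len(ref)
        for rec, (surv, acc, elim) in zip(trace.rounds, ref):
            assert rec.surviving == surv
            assert rec.eliminated == elim
            assert rec.mean_test_accuracy == pytest.approx(acc, abs=1e-12)

    def test_pure_noise_accuracy_near_chance(self):
        rng = np.random.default_rng(11)
        ds = make_dataset(rng.normal(size=(30, 24)), n_case=12)
        splits = make_splits(ds, n_splits=10, master_seed=2)
        (group,) = group_splits(splits, n_groups=1, master_seed=2)
        trace, sig = run_group(ds, group, min_genes=5)
        # chosen round is the max over a noisy ~0.5 curve; allow headroom
        assert trace.best_round().mean_test_accuracy < 0.8

    def test_same_seed_identical_trace(self, easy_study):
        ds, _ = easy_study
        splits = make_splits(ds, n_splits=10, master_seed=7)
        (group,) = group_splits(splits, n_groups=1, master_seed=7)
        t1, s1 = run_group(ds, group)
        t2, s2 = run_group(ds, group)
        assert s1.genes == s2.genes
        assert [r.eliminated for r in t1.rounds] == [r.eliminated for r in t2.rounds]

    def test_surviving_sets_strictly_decrease(self, easy_study):
        ds, _ = easy_study
        splits = make_splits(ds, n_splits=10, master_seed=3)
        (group,) = group_splits(splits, n_groups=1, master_seed=3)
        trace, _ = run_group(ds, group)
        sizes = [len(r.surviving) for r in trace.rounds]
        assert all(a > b for a, b in zip(sizes, sizes[1:]))
        assert len(trace.rounds) <= ds.n_genes


class TestSignatureCombination:
    def test_intersection_of_groups(self):
        sigs = [
            Signature(["a", "b", "c"], {"group": 1}),
            Signature(["a", "b"], {"group": 2}),
            Signature(["a", "b", "d"], {"group": 3}),
        ]
        out = intersect_groups(sigs)
        assert out.genes == ("a", "b")
        assert out.provenance["groups"] == [1, 2, 3]

    def test_single_group_identity(self):
        sig = Signature(["x", "y"], {"group": 1})
        assert intersect_groups([sig]).genes == ("x", "y")

    def test_disjoint_groups_flagged_empty(self):
        out = intersect_groups([Signature(["a"]), Signature(["b"])])
        assert out.is_empty
        assert out.provenance["empty"] is True

    def test_majority_threshold_at_half(self):
        sigs = (
            [Signature(["x", "y", "z"])] * 2
            + [Signature(["x", "y"])] * 1
            + [Signature(["x"])] * 1
            + [Signature(["q"])] * 2
        )
        # votes over 6 studies: x:4, y:3, z:2, q:2 -> need >= 3
        out = majority_signature(sigs, fraction=0.5)
        assert out.genes == ("x", "y")
        assert out.provenance["votes"] == {"x": 4, "y": 3}

    def test_fraction_one_equals_intersection(self):
        sigs = [Signature(["a", "b"]), Signature(["a", "c"]), Signature(["a", "b"])]
        assert majority_signature(sigs, fraction=1.0).genes == ("a",)

    def test_six_study_example(self):
        in3 = [Signature(["g"])] * 3 + [Signature(["h"])] * 3
        assert "g" in majority_signature(in3, 0.5)
        in2 = [Signature(["g"])] * 2 + [Signature(["h"])] * 4
        assert "g" not in majority_signature(in2, 0.5)


class TestConsensusRFEModel:
    def test_fit_is_deterministic_and_reports(self):
        cfg = SimulationConfig(
            n_genes=40, n_signal_genes=6, n_case=10, n_control=10,
            n_studies=2, effect_size=2.0, label_noise=0.0, outlier_fraction=0.0, seed=2,
        )
        ds, _ = simulate_study(cfg, 0)
        model = ConsensusRFE(ds, n_splits=12, n_groups=3, min_genes=4, master_seed=2)
        r1, r2 = model.fit(), model.fit()
        assert r1.signature.genes == r2.signature.genes
        assert len(r1.group_signatures) == 3
        assert r1.signature.provenance["master_seed"] == 2
        text = r1.summary()
        assert "consensus signature" in text and ds.study_id in text
        log = r1.round_log()
        assert set(log["group"]) == {1, 2, 3}

    def test_indivisible_split_count_rejected(self, toy_separable):
        with pytest.raises(ValueError, match="divisible"):
            ConsensusRFE(toy_separable, n_splits=10, n_groups=3)
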