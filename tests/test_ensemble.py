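import numpy as np
import pytest

import oracles
from epigain.ensemble import (
    CVReport,
    GBMAdapter,
    LearnerAdapter,
    MajorityAdapter,
    OracleAdapter,
    ParamGrid,
    RandomForestAdapter,
    aggregate_importance,
    average_cv_accuracy,
    consensus_select,
    cv_auc,
    repeated_cv,
    stratified_kfold,
    tune,
)
from epigain.genotype import GenotypeMatrix, Phenotype
from epigain.relief import ImportanceTable


def _dataset(n=100, p=8, seed=0, balanced=True):
    rng = np.random.default_rng(seed)
    geno = rng.integers(0, 3, (n, p)).astype(np.int8)
    if balanced:
        y = np.array([0, 1] * (n // 2))
    else:
        y = rng.integers(0, 2, n)
    g = GenotypeMatrix(geno, [f"rs{j}" for j in range(p)],
                       [f"s{i}" for i in range(n)])
    return g, Phenotype(y)


class TestStratifiedKFold:
    def test_balanced_folds_partition_all_samples(self):
        _, phen = _dataset(100)
        folds = stratified_kfold(phen, k=10, seed=1)
        sizes = [f.size for f in folds]
        assert sizes == [10] * 10
        allidx = np.concatenate(folds)
        assert sorted(allidx.tolist()) == list(range(100))
        for f in folds:
            assert phen.labels[f].sum() == 5  # 5 cases, 5 controls per fold

    def test_class_balance_within_one_sample(self):
        rng = np.random.default_rng(2)
        y = np.array([1] * 37 + [0] * 63)
        phen = Phenotype(rng.permutation(y))
        folds = stratified_kfold(phen, k=5, seed=3)
        case_counts = [phen.labels[f].sum() for f in folds]
        assert max(case_counts) - min(case_counts) <= 1

    def test_seed_determinism_and_small_class_error(self):
        _, phen = _dataset(60)
        f1 = stratified_kfold(phen, k=6, seed=9)
        f2 = stratified_kfold(phen, k=6, seed=9)
        assert all(np.array_equal(a, b) for a, b in zip(f1, f2))
        tiny = Phenotype(np.array([1] * 3 + [0] * 30))
        with pytest.raises(ValueError, match="fewer than k"):
            stratified_kfold(tiny, k=5)


class TestRepeatedCV:
    def test_oracle_adapter_scores_perfect_accuracy(self):
        g, phen = _dataset(60)
        frac, prob, _ = repeated_cv(g, phen, OracleAdapter(phen.labels), {},
                                    k=5, repeats=3, seed=0)
        assert average_cv_accuracy(frac) == 1.0
        assert np.all(frac == 1.0)

    def test_majority_adapter_on_balanced_data_scores_half(self):
        g, phen = _dataset(80)
        frac, prob, _ = repeated_cv(g, phen, MajorityAdapter(), {},
                                    k=5, repeats=2, seed=0)
        # training majority prob is exactly 0.5 on balanced folds: the 0.5
        # threshold classifies everyone as case, so accuracy is 0.5
        assert average_cv_accuracy(frac) == 0.5

    def test_per_sample_fractions_lie_on_repeats_grid(self):
        g, phen = _dataset(60, seed=5)
        frac, _, _ = repeated_cv(g, phen, RandomForestAdapter(),
                                 {"ntree": 20, "mtry": 2}, k=5, repeats=10, seed=1)
        grid = np.round(frac * 10)
        assert np.allclose(frac, grid / 10)

    def test_adapter_failure_names_fold_and_repeat(self):
        class Broken(LearnerAdapter):
            name = "broken"

            def fit(self, X, y, params, seed):
                raise RuntimeError("boom")

        g, phen = _dataset(40)
        with pytest.raises(RuntimeError, match="fold 0, repeat 0"):
            repeated_cv(g, phen, Broken(), {}, k=4, repeats=1, seed=0)


class TestMetrics:
    def test_auc_extremes(self):
        phen = Phenotype(np.array([0, 0, 1, 1]))
        assert cv_auc(np.array([0.1, 0.2, 0.8, 0.9]), phen) == 1.0
        assert cv_auc(np.array([0.9, 0.8, 0.2, 0.1]), phen) == 0.0

    def test_auc_matches_pair_counting_oracle_on_hand_listed_samples(self):
        probs = np.array([0.1, 0.9, 0.4, 0.4, 0.6, 0.3, 0.8, 0.2, 0.55, 0.45,
                          0.5, 0.5, 0.7, 0.35, 0.65, 0.25, 0.15, 0.95, 0.4, 0.6])
        labels = np.array([0, 1, 0, 1, 1, 0, 1, 0, 1, 0,
                           1, 0, 1, 0, 1, 0, 0, 1, 1, 0])
        phen = Phenotype(labels)
        assert cv_auc(probs, phen) == pytest.approx(
            oracles.auc_pair_counting(probs, labels), abs=1e-12)

    def test_auc_rejects_single_class(self):
        with pytest.raises(ValueError, match="single-class"):
            cv_auc(np.array([0.5, 0.5]), Phenotype(np.array([1, 1])))


class TestTune:
    def test_single_cell_grid_wins(self):
        g, phen = _dataset(40)
        rep = tune(g, phen, MajorityAdapter(), ParamGrid({"x": [1]}),
                   k=4, repeats=1, seed=0)
        assert rep.winner == {"x": 1}

    def test_duplicated_cells_get_identical_metrics(self):
        g, phen = _dataset(40, seed=3)
        rep = tune(g, phen, RandomForestAdapter(),
                   ParamGrid({"ntree": [10, 10], "mtry": [2]}),
                   k=4, repeats=1, seed=7)
        assert rep.accuracy[0] == rep.accuracy[1]
        assert rep.auc[0] == rep.auc[1]

    def test_winner_maximises_accuracy_with_auc_tiebreak(self):
        rep = CVReport(cells=[{"a": 1}, {"a": 2}, {"a": 3}],
                       accuracy=[0.6, 0.7, 0.7], auc=[0.9, 0.65, 0.8])
        assert rep.pick_winner() == {"a": 3}
        rep2 = CVReport(cells=[{"a": 1}, {"a": 2}], accuracy=[0.7, 0.7],
                        auc=[0.8, 0.8])
        assert rep2.pick_winner() == {"a": 1}  # first in grid order


class TestImportanceAggregation:
    def test_identical_vectors_average_to_themselves(self):
        v = np.array([0.0, 2.0, 1.0])
        t = aggregate_importance([v, v, v], ["a", "b", "c"], "rf")
        assert t.scores == pytest.approx([0.0, 1.0, 0.5])  # min-max normalised

    def test_opposite_vectors_tie_after_averaging(self):
        t = aggregate_importance([np.array([0.0, 2.0]), np.array([2.0, 0.0])],
                                 ["a", "b"], "rf")
        assert t.scores[0] == t.scores[1]

    def test_mean_matches_independent_recomputation(self):
        rng = np.random.default_rng(11)
        vecs = [rng.random(7) for _ in range(100)]
        t = aggregate_importance(vecs, [f"r{i}" for i in range(7)], "gbm")
        mean = sum(vecs) / 100
        expect = (mean - mean.min()) / (mean.max() - mean.min())
        assert t.scores == pytest.approx(expect, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            aggregate_importance([np.zeros(3), np.zeros(4)], ["a", "b", "c"], "rf")


class TestConsensus:
    def test_top_k_intersection(self):
        rf = ImportanceTable(["A", "B", "C"], np.array([3.0, 2.0, 1.0]), "rf")
        gbm = ImportanceTable(["A", "B", "C"], np.array([2.0, 3.0, 1.0]), "gbm")
        assert consensus_select(rf, gbm, rule="top_k", k=2) == {"A", "B"}

    def test_diagonal_bounds(self):
        rng = np.random.default_rng(0)
        ids = [f"r{i}" for i in range(20)]
        rf = ImportanceTable(ids, rng.random(20), "rf")
        gbm = ImportanceTable(ids, rng.random(20), "gbm")
        assert consensus_select(rf, gbm, rule="diagonal", t=0.0) == set(ids)
        maximal = consensus_select(rf, gbm, rule="diagonal", t=2.0)
        assert maximal == {ids[i] for i in range(20)
                           if rf.scores[i] + gbm.scores[i] >= 2.0}

    def test_diagonal_equals_brute_force_sum_scan(self):
        rng = np.random.default_rng(8)
        ids = [f"r{i}" for i in range(50)]
        rf = ImportanceTable(ids, rng.random(50), "rf")
        gbm = ImportanceTable(ids, rng.random(50), "gbm")
        t = 1.1
        expect = {ids[i] for i in range(50) if rf.scores[i] + gbm.scores[i] >= t}
        assert consensus_select(rf, gbm, rule="diagonal", t=t) == expect

    def test_mismatched_ids_rejected(self):
        rf = ImportanceTable(["A"], np.array([1.0]), "rf")
        gbm = ImportanceTable(["B"], np.array([1.0]), "gbm")
        with pytest.raises(ValueError, match="snp_ids"):
            consensus_select(rf, gbm)


class TestRealLearnersSmoke:
    def test_rf_and_gbm_find_a_strong_main_effect(self):
        rng = np.random.default_rng(42)
        n = 200
        y = np.array([0, 1] * (n // 2))
        geno = rng.integers(0, 3, (n, 6)).astype(np.int8)
        geno[:, 4] = np.where(y == 1, 2, 0)  # deterministic marker
        g = GenotypeMatrix(geno, [f"rs{j}" for j in range(6)],
                           [f"s{i}" for i in range(n)])
        phen = Phenotype(y)
        for adapter, params in ((RandomForestAdapter(), {"ntree": 50, "mtry": 2}),
                                (GBMAdapter(), {"n_trees": 50,
                                                "interaction_depth": 2,
                                                "shrinkage": 0.1})):
            frac, prob, imps = repeated_cv(g, phen, adapter, params,
                                           k=4, repeats=2, seed=0)
            assert average_cv_accuracy(frac) > 0.95
            table = aggregate_importance(imps, g.snp_ids, adapter.name)
            assert table.ranking()[0] == "rs4"
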