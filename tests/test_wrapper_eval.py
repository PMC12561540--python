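import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from efsel.data_io import ValidationError, stratified_split
from efsel.optimizers import Individual
from efsel.synthetic_data import SynthSpec, generate
from efsel.wrapper_eval import (
    FitnessSpec,
    WrapperEvaluator,
    cv_accuracy,
    evaluate_individual,
    fitness,
    knn_predict,
    validate_on_test,
)


from conftest import brute_force_knn


class TestKnnPredict:
    def test_k1_query_on_training_row(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        y = np.array([0, 1, 0])
        assert knn_predict(X, y, X[1:2], 1)[0] == 1

    def test_k_equals_train_size_gives_majority(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(10, 3))
        y = np.array([0] * 7 + [1] * 3)
        pred = knn_predict(X, y, rng.uniform(size=(4, 3)), 10)
        assert np.all(pred == 0)

    def test_five_nearest_majority(self):
        # one query at origin, neighbors at increasing distance: labels 0,0,1,1,1
        X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [50.0]])
        y = np.array([0, 0, 1, 1, 1, 0])
        assert knn_predict(X, y, np.array([[0.0]]), 5)[0] == 1

    def test_k_larger_than_train_rejected(self):
        with pytest.raises(ValidationError):
            knn_predict(np.zeros((3, 2)), np.array([0, 1, 0]), np.zeros((1, 2)), 4)

    def test_vote_tie_broken_by_closest_member(self):
        # 2 votes each; class 1's nearest member is closer
        X = np.array([[1.0], [1.5], [2.0], [3.0]])
        y = np.array([1, 0, 1, 0])
        assert knn_predict(X, y, np.array([[0.0]]), 4)[0] == 1

    def test_residual_tie_broken_by_smallest_label(self):
        # identical distances and symmetric votes -> smallest label wins
        X = np.array([[1.0], [-1.0]])
        y = np.array([1, 0])
        assert knn_predict(X, y, np.array([[0.0]]), 2)[0] == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_train = rng.integers(6, 50)
        n_feat = rng.integers(1, 6)
        X = rng.uniform(size=(n_train, n_feat))
        y = rng.integers(0, 3, size=n_train)
        Q = rng.uniform(size=(8, n_feat))
        k = int(rng.integers(1, min(6, n_train)))
        np.testing.assert_array_equal(
            knn_predict(X, y, Q, k), brute_force_knn(X, y, Q, k)
        )


class TestCvAccuracy:
    def test_class_determining_feature_scores_one(self, tiny_dataset):
        mask = np.array([True, False, False])
        acc = cv_accuracy(tiny_dataset, np.arange(12), mask, FitnessSpec(cv_folds=3), 0)
        assert acc == 1.0

    def test_permuted_labels_near_chance(self):
        ds, _ = generate(
            SynthSpec(n_samples=200, n_classes=2, n_informative=5,
                      class_separation=4.0, seed=3)
        )
        rng = np.random.default_rng(4)
        ds.y = rng.permutation(ds.y)
        mask = np.ones(ds.n_features, dtype=bool)
        acc = cv_accuracy(ds, np.arange(200), mask, FitnessSpec(), 0)
        assert abs(acc - 0.5) <= 0.1

    def test_invariant_to_feature_order(self, noisy_dataset):
        ds, truth = noisy_dataset
        acc1 = cv_accuracy(ds, np.arange(ds.n_samples), truth, FitnessSpec(), 5)
        perm = np.random.default_rng(1).permutation(ds.n_features)
        ds2 = type(ds)(X=ds.X[:, perm], y=ds.y,
                       feature_names=[ds.feature_names[j] for j in perm])
        acc2 = cv_accuracy(ds2, np.arange(ds.n_samples), truth[perm], FitnessSpec(), 5)
        assert acc1 == pytest.approx(acc2)

    def test_empty_mask_is_contract_error(self, tiny_dataset):
        with pytest.raises(ValidationError):
            cv_accuracy(tiny_dataset, np.arange(12),
                        np.zeros(3, dtype=bool), FitnessSpec(), 0)


class TestFitness:
    def test_arithmetic_examples(self):
        assert fitness(1.0, 10, 10, 0.9) == pytest.approx(0.1)
        assert fitness(0.8, 5, 10, 0.5) == pytest.approx(0.35)
        assert fitness(1.0, 0, 10, 0.5) == 0.0

    def test_beta_bounds_enforced(self):
        with pytest.raises(ValidationError):
            fitness(0.5, 1, 2, 1.0)
        with pytest.raises(ValidationError):
            fitness(0.5, 1, 2, 0.0)

    @given(
        acc=st.floats(0, 1),
        size=st.integers(0, 50),
        beta=st.floats(0.01, 0.99),
    )
    @settings(derandomize=True, max_examples=100)
    def test_bounded_and_monotone(self, acc, size, beta):
        f = fitness(acc, size, 50, beta)
        assert 0.0 <= f <= 1.0
        if acc < 1:
            assert fitness(min(acc + 0.01, 1.0), size, 50, beta) < f or acc + 0.01 > 1
        if size < 50:
            assert fitness(acc, size + 1, 50, beta) > f


class TestEvaluateIndividual:
    def test_worst_fitness_policy(self, tiny_dataset):
        ind = Individual(genotype=np.full(3, 0.05))
        res = evaluate_individual(ind, 0.5, tiny_dataset, np.arange(12),
                                  FitnessSpec(cv_folds=3), 0)
        assert res.fitness == 1.0 and res.accuracy == 0.0 and res.subset_size == 0
        assert ind.fitness == 1.0

    def test_repair_policy_selects_strongest_gene(self, tiny_dataset):
        ind = Individual(genotype=np.array([0.4, 0.1, 0.3]))
        spec = FitnessSpec(cv_folds=3, empty_subset_policy="repair")
        res = evaluate_individual(ind, 0.5, tiny_dataset, np.arange(12), spec, 0)
        assert res.subset_size == 1
        assert res.accuracy == 1.0  # gene 0 is the class-determining feature

    def test_deterministic_given_seed(self, noisy_dataset):
        ds, _ = noisy_dataset
        ind = Individual(genotype=np.random.default_rng(0).uniform(size=ds.n_features))
        r1 = evaluate_individual(ind, 0.5, ds, np.arange(ds.n_samples), FitnessSpec(), 7)
        r2 = evaluate_individual(ind, 0.5, ds, np.arange(ds.n_samples), FitnessSpec(), 7)
        assert r1 == r2

    def test_evaluator_class_matches_free_function(self, noisy_dataset):
        ds, _ = noisy_dataset
        train = np.arange(ds.n_samples)
        ev = WrapperEvaluator(ds, train, FitnessSpec(), seed=9)
        ind = Individual(genotype=np.random.default_rng(2).uniform(size=ds.n_features))
        res_class = ev(ind, 0.5)
        res_free = evaluate_individual(
            ind, 0.5, ds, train, FitnessSpec(), 9, folds=ev.folds
        )
        assert res_class == res_free


class TestValidateOnTest:
    def test_truth_mask_on_separable_data(self, separable_dataset):
        ds, truth = separable_dataset
        split = stratified_split(ds, 0.7, seed=0)
        genotype = np.where(truth, 0.9, 0.1)
        best = Individual(genotype=genotype)
        acc, size = validate_on_test(best, 0.5, ds, split, FitnessSpec())
        assert acc > 0.95
        assert size == truth.sum()

    def test_pure_noise_mask_near_chance(self):
        accs = []
        for seed in range(4):
            ds, truth = generate(
                SynthSpec(n_samples=200, n_classes=2, n_informative=2,
                          n_noise=20, class_separation=5.0, seed=seed)
            )
            split = stratified_split(ds, 0.7, seed=seed)
            best = Individual(genotype=np.where(truth, 0.1, 0.9))
            acc, _ = validate_on_test(best, 0.5, ds, split, FitnessSpec())
            accs.append(acc)
        assert abs(np.mean(accs) - 0.5) <= 0.15

    def test_independent_of_test_row_order(self, separable_dataset):
        ds, truth = separable_dataset
        split = stratified_split(ds, 0.7, seed=1)
        best = Individual(genotype=np.where(truth, 0.9, 0.1))
        acc1, _ = validate_on_test(best, 0.5, ds, split, FitnessSpec())
        shuffled = type(split)(
            train_indices=split.train_indices,
            test_indices=np.random.default_rng(0).permutation(split.test_indices),
            seed=split.seed,
        )
        acc2, _ = validate_on_test(best, 0.5, ds, shuffled, FitnessSpec())
        assert acc1 == pytest.approx(acc2)
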