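import itertools

import numpy as np
import pytest

from plumspec.evaluation import make_split
from plumspec.models import ModelSpec
from plumspec.selection import (
    ALGORITHM_DEFAULTS,
    FitnessEvaluator,
    OptimizerConfig,
    evaluate_subset_fitness,
    exhaustive_search,
    run_selector,
    summarize_selectors,
)


@pytest.fixture()
def small_problem(rng):
    """8 wavelengths, the first two informative, activity-scale response."""
    n = 40
    X = rng.normal(size=(n, 8))
    y = 0.002 * X[:, 0] + 0.001 * X[:, 1] + 0.0004 * rng.normal(size=n)
    w = np.linspace(520, 660, 8)
    split = make_split(n, seed=5)
    return X, y, w, split


class TestFitnessEvaluator:
    def test_full_mask_matches_unwrapped_pipeline(self, small_problem):
        from plumspec.models import fit, predict

        X, y, w, split = small_problem
        mask = np.ones(8, dtype=bool)
        fitness = evaluate_subset_fitness(mask, X, y, w, split)
        spec = ModelSpec("svr", kernel="linear")
        model = fit(spec, X[split.train], y[split.train], w)
        pred = predict(model, X[split.validation])
        rmse = float(np.sqrt(np.mean((y[split.validation] - pred) ** 2)))
        assert fitness == pytest.approx(rmse, abs=1e-12)

    def test_empty_mask_is_infinite_not_an_error(self, small_problem):
        X, y, w, split = small_problem
        assert evaluate_subset_fitness(np.zeros(8, bool), X, y, w, split) == np.inf

    def test_memoization_counts_calls_and_refits(self, small_problem):
        X, y, w, split = small_problem
        ev = FitnessEvaluator(X, y, w, split)
        mask = np.zeros(8, bool)
        mask[:2] = True
        f1 = ev.evaluate(mask)
        f2 = ev.evaluate(mask)
        assert f1 == f2
        assert ev.n_calls == 2 and ev.n_unique == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_informative_subset_beats_disjoint_random_subset(self, seed):
        """The planted wavelengths of a generated dataset always score a
        strictly lower validation RMSE than an equally sized disjoint
        random subset."""
        from plumspec import GeneratorConfig, generate_dataset, truncate_wavelengths

        spectra, reference, truth = generate_dataset(GeneratorConfig(seed=seed))
        spectra = truncate_wavelengths(spectra)
        y = reference.aligned_to(spectra)
        w = spectra.wavelengths_nm
        split = make_split(160, seed=seed)
        planted = np.zeros(w.size, bool)
        for p in truth.planted_wavelengths_nm:
            planted[int(np.argmin(np.abs(w - p)))] = True
        rng = np.random.default_rng(seed)
        candidates = np.flatnonzero(~planted & (w > 750))  # far from any bump
        random_mask = np.zeros(w.size, bool)
        random_mask[rng.choice(candidates, size=int(planted.sum()), replace=False)] = True
        ev = FitnessEvaluator(spectra.absorbance, y, w, split)
        assert ev.evaluate(planted) < ev.evaluate(random_mask)


class TestExhaustiveSearch:
    def test_evaluation_count_five_candidates_k2(self, small_problem):
        X, y, w, split = small_problem
        _, _, count = exhaustive_search(X[:, :5], y, w[:5], split, k=2)
        assert count == 15  # C(5,1) + C(5,2)

    def test_returns_the_minimum(self, small_problem):
        X, y, w, split = small_problem
        mask, fstar, _ = exhaustive_search(X[:, :5], y, w[:5], split, k=2)
        ev = FitnessEvaluator(X[:, :5], y, w[:5], split)
        for subset in itertools.chain(
            itertools.combinations(range(5), 1), itertools.combinations(range(5), 2)
        ):
            m = np.zeros(5, bool)
            m[list(subset)] = True
            assert fstar <= ev.evaluate(m) + 1e-15

    def test_agrees_with_independent_nested_loops(self, small_problem):
        X, y, w, split = small_problem
        mask, fstar, _ = exhaustive_search(X[:, :6], y, w[:6], split, k=2)
        ev = FitnessEvaluator(X[:, :6], y, w[:6], split)
        best, best_subset = np.inf, None
        for i in range(6):
            m = np.zeros(6, bool)
            m[i] = True
            f = ev.evaluate(m)
            if f < best:
                best, best_subset = f, (i,)
        for i in range(6):
            for j in range(i + 1, 6):
                m = np.zeros(6, bool)
                m[[i, j]] = True
                f = ev.evaluate(m)
                if f < best:
                    best, best_subset = f, (i, j)
        assert fstar == pytest.approx(best, abs=1e-15)
        assert tuple(np.flatnonzero(mask)) == best_subset

    def test_combinatorial_bound_checked_before_evaluation(self, small_problem):
        X, y, w, split = small_problem
        with pytest.raises(ValueError, match="exceed"):
            exhaustive_search(X, y, w, split, k=8, max_subsets=10)


class TestRunSelector:
    def test_single_candidate_pool(self, rng):
        n = 30
        X = rng.normal(size=(n, 1))
        y = 0.01 * X[:, 0] + 0.001 * rng.normal(size=n)
        split = make_split(n, seed=1)
        res = run_selector(
            OptimizerConfig(algorithm="ga", k_max=1, iterations=4, seed=0),
            X, y, np.array([600.0]), split,
        )
        assert res.best_wavelengths_nm.tolist() == [600.0]
        assert np.ptp(res.trace) == 0.0

    @pytest.mark.parametrize("algorithm", sorted(ALGORITHM_DEFAULTS))
    def test_traces_monotone_and_budget_respected(self, algorithm, small_problem):
        X, y, w, split = small_problem
        cfg = OptimizerConfig(algorithm=algorithm, k_max=3, iterations=8, seed=3, n_runs=2)
        res = run_selector(cfg, X, y, w, split)
        for trace in res.per_run_traces:
            assert len(trace) == 8
            assert np.all(np.diff(trace) <= 1e-15)
        assert res.best_fitness == min(res.per_run_fitness)
        assert 1 <= res.n_selected <= 3
        # every fitness request went through the memoizing evaluator
        assert res.unique_evaluations <= res.evaluation_count

    def test_deterministic_under_seed(self, small_problem):
        X, y, w, split = small_problem
        cfg = OptimizerConfig(algorithm="pso", k_max=3, iterations=6, seed=11)
        a = run_selector(cfg, X, y, w, split)
        b = run_selector(cfg, X, y, w, split)
        np.testing.assert_array_equal(a.best_mask, b.best_mask)
        np.testing.assert_array_equal(a.trace, b.trace)

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            OptimizerConfig(algorithm="simulated_annealing")

    def test_zero_iteration_budget_rejected(self):
        with pytest.raises(ValueError, match="iteration"):
            OptimizerConfig(algorithm="pso", iterations=0)

    def test_selector_never_beats_exhaustive_optimum(self, small_problem):
        X, y, w, split = small_problem
        _, fstar, _ = exhaustive_search(X, y, w, split, k=3)
        for algorithm in ("pso", "ga", "la"):
            res = run_selector(
                OptimizerConfig(algorithm=algorithm, k_max=3, iterations=10, seed=2),
                X, y, w, split,
            )
            assert res.best_fitness >= fstar - 1e-15


class TestSummarize:
    def test_single_run_row_echoes_values(self, small_problem):
        X, y, w, split = small_problem
        res = run_selector(OptimizerConfig(algorithm="ga", k_max=3, iterations=4, seed=0),
                           X, y, w, split)
        table = summarize_selectors([res])
        assert len(table) == 1
        row = table.iloc[0]
        assert row["algorithm"] == "ga"
        assert row["mean_fitness_rmse"] == pytest.approx(res.per_run_fitness[0])
        assert row["n_selected"] == res.n_selected

    def test_means_match_hand_computation_and_sorting(self, small_problem):
        X, y, w, split = small_problem
        results = [
            run_selector(OptimizerConfig(algorithm=a, k_max=3, iterations=4, seed=0, n_runs=2),
                         X, y, w, split)
            for a in ("ga", "pso")
        ]
        table = summarize_selectors(results)
        assert len(table) == 2
        for r in results:
            row = table[table["algorithm"] == r.algorithm].iloc[0]
            assert row["mean_fitness_rmse"] == pytest.approx(float(np.mean(r.per_run_fitness)))
            assert row["mean_test_correlation"] == pytest.approx(
                float(np.mean(r.per_run_test_correlation))
            )
        assert table["mean_fitness_rmse"].is_monotonic_increasing
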