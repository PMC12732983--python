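import itertools

import numpy as np
import pytest
from scipy import stats

from plumspec.evaluation import (
    MetricsReport,
    PartitionMetrics,
    ProtocolResult,
    association_test,
    classify_rpd,
    compute_metrics,
    make_split,
    paired_model_test,
    run_protocol,
    select_best_split,
)
from plumspec.models import ModelSpec
from plumspec.preprocessing import PreprocessingSpec


class TestComputeMetrics:
    def test_perfect_prediction(self, rng):
        d = rng.normal(size=20)
        m = compute_metrics(d, d)
        assert m.rmse == 0.0 and m.r2 == pytest.approx(1.0) and np.isinf(m.rpd)
        assert m.rpd_class == "excellent"

    def test_two_point_hand_case(self):
        m = compute_metrics([0.0, 2.0], [0.0, 0.0])
        assert m.rmse == pytest.approx(np.sqrt(2.0), abs=1e-12)
        assert m.sd == pytest.approx(np.sqrt(2.0), abs=1e-12)
        assert m.rpd == pytest.approx(1.0, abs=1e-12)

    def test_matches_textbook_formulas(self, rng):
        d = rng.normal(size=50)
        p = d + 0.3 * rng.normal(size=50)
        m = compute_metrics(d, p)
        assert m.rmse == pytest.approx(np.sqrt(((d - p) ** 2).sum() / 50), abs=1e-12)
        assert m.sd == pytest.approx(np.sqrt(((d - d.mean()) ** 2).sum() / 49), abs=1e-12)
        assert m.rpd == pytest.approx(m.sd / m.rmse, abs=1e-12)
        assert m.r2 == pytest.approx(stats.pearsonr(d, p).statistic ** 2, abs=1e-12)

    def test_rpd_times_rmse_identity(self, rng):
        for _ in range(20):
            d = rng.normal(size=30)
            p = rng.normal(size=30)
            m = compute_metrics(d, p)
            assert m.rpd * m.rmse == pytest.approx(m.sd, rel=1e-12)

    def test_variance_form_rpd_identity(self, rng):
        """With the variance-form R2 (same SD convention), RPD equals
        1/sqrt(1 - R2) exactly."""
        for _ in range(20):
            d = rng.normal(size=30)
            p = d + rng.normal(size=30)
            m = compute_metrics(d, p)
            assert m.rpd == pytest.approx(1.0 / np.sqrt(1.0 - m.r2_variance), rel=1e-12)

    def test_constant_observed_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            compute_metrics(np.full(5, 1.0), np.arange(5.0))

    def test_constant_predicted_flagged(self, rng):
        m = compute_metrics(rng.normal(size=10), np.full(10, 0.5))
        assert m.constant_predicted and m.r2 == 0.0


class TestClassifyRpd:
    @pytest.mark.parametrize(
        "rpd,label",
        [
            (2.4, "very good"),    # printed classification of the best SVR
            (0.82, "very poor"),   # printed classification of the weak PLSR
            (5.69, "excellent"),   # printed classification of the best DT
            (0.0, "very poor"),
            (1.0, "weak"),
            (1.4, "acceptable"),
            (1.8, "good"),
            (2.0, "very good"),
            (2.5, "very good"),
            (2.51, "excellent"),
            (float("inf"), "excellent"),
        ],
    )
    def test_band_assignment(self, rpd, label):
        assert classify_rpd(rpd) == label

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_rpd(-0.1)


class TestMakeSplit:
    def test_160_gives_96_32_32(self):
        s = make_split(160, seed=1)
        assert (s.train.size, s.validation.size, s.test.size) == (96, 32, 32)

    def test_ten_gives_6_2_2_disjoint_covering(self):
        s = make_split(10, seed=2)
        assert (s.train.size, s.validation.size, s.test.size) == (6, 2, 2)
        together = np.concatenate([s.train, s.validation, s.test])
        assert sorted(together.tolist()) == list(range(10))

    def test_seed_determinism_and_sensitivity(self):
        base = make_split(60, seed=0)
        same = make_split(60, seed=0)
        np.testing.assert_array_equal(base.train, same.train)
        distinct = sum(
            not np.array_equal(base.train, make_split(60, seed=s).train)
            for s in range(1, 21)
        )
        assert distinct == 20

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            make_split(4)


class TestRunProtocol:
    @pytest.fixture()
    def tiny_problem(self, rng):
        X = rng.normal(size=(30, 8))
        y = X[:, 0] * 0.01 + 0.002 * rng.normal(size=30)
        w = np.linspace(510, 580, 8)
        return X, y, w

    def test_single_cell_single_rep(self, tiny_problem):
        X, y, w = tiny_problem
        res = run_protocol(X, y, w, [PreprocessingSpec("none")], [ModelSpec("dt")], n_reps=1)
        assert len(res.records) == 1
        assert isinstance(res.records[0]["report"], MetricsReport)

    def test_grid_cardinality(self, tiny_problem):
        X, y, w = tiny_problem
        preps = [PreprocessingSpec("none"), PreprocessingSpec("snv")]
        models = [ModelSpec("dt"), ModelSpec("svr", kernel="linear"), ModelSpec("plsr", n_components=2)]
        res = run_protocol(X, y, w, preps, models, n_reps=5)
        assert len(res.records) == 2 * 3 * 5

    def test_bit_identical_reruns(self, tiny_problem):
        X, y, w = tiny_problem
        kw = dict(
            preprocessing_grid=[PreprocessingSpec("none")],
            model_grid=[ModelSpec("svr", kernel="rbf")],
            n_reps=6,
            base_seed=3,
        )
        a = run_protocol(X, y, w, **kw).to_frame()
        b = run_protocol(X, y, w, **kw).to_frame()
        assert a.equals(b)

    def test_failing_cell_recorded_not_raised(self, tiny_problem):
        X, y, w = tiny_problem
        res = run_protocol(
            X, y, w, [PreprocessingSpec("none")],
            [ModelSpec("plsr", n_components=9)],  # exceeds the rank bound
            n_reps=1,
        )
        assert res.records[0]["report"] is None
        assert "exceeds" in res.records[0]["error"]


def _fake_result(test_rpds, val_rpds):
    """ProtocolResult with one cell per repetition and prescribed RPDs."""
    def pm(rpd):
        return PartitionMetrics(n=10, r2=0.5, r2_variance=0.5, rmse=1.0, sd=rpd,
                                rpd=rpd, rpd_class=classify_rpd(rpd))
    res = ProtocolResult(n_reps=len(test_rpds))
    for i, (t, v) in enumerate(zip(test_rpds, val_rpds)):
        res.records.append(
            {"rep": i, "seed": i, "preprocessing": "none", "model": "dt-10",
             "report": MetricsReport(pm(2.0), pm(v), pm(t))}
        )
    return res


class TestSelectBestSplit:
    def test_dominant_repetition_wins(self):
        res = _fake_result([1.0, 3.0, 2.0], [1.0, 3.0, 2.0])
        assert select_best_split(res) == 1

    def test_tie_resolves_to_lower_index(self):
        res = _fake_result([2.0, 2.0, 1.0], [2.0, 2.0, 2.0])
        assert select_best_split(res) == 0

    def test_validation_guard_excludes_lucky_test_sets(self):
        # rep 2 has the best test RPD but below-median validation RPD
        res = _fake_result([1.0, 2.0, 9.0, 1.5], [3.0, 3.0, 0.5, 3.0])
        assert select_best_split(res) == 1

    def test_matches_independent_rule_reimplementation(self, rng):
        test_rpds = rng.uniform(0.5, 4.0, 10).round(3).tolist()
        val_rpds = rng.uniform(0.5, 4.0, 10).round(3).tolist()
        res = _fake_result(test_rpds, val_rpds)
        med = float(np.median(val_rpds))
        eligible = [i for i in range(10) if val_rpds[i] >= med]
        expected = min(
            (i for i in eligible if test_rpds[i] == max(test_rpds[j] for j in eligible))
        )
        assert select_best_split(res) == expected

    def test_no_successful_repetition_rejected(self):
        res = ProtocolResult()
        res.records.append({"rep": 0, "report": None, "error": "x"})
        with pytest.raises(ValueError):
            select_best_split(res)


class TestAssociationTest:
    def test_perfect_correlation_tiny_p(self, rng):
        d = rng.normal(size=10)
        assert association_test(d, d) < 1e-10

    def test_exactly_zero_correlation_gives_one(self):
        d = np.array([1.0, 0.0, -1.0, 2.0, 0.0, -2.0])
        p = np.array([0.0, 1.0, 0.0, 0.0, -1.0, 0.0])
        r = np.corrcoef(d, p)[0, 1]
        assert r == pytest.approx(0.0, abs=1e-12)
        assert association_test(d, p) == pytest.approx(1.0, abs=1e-10)

    def test_null_pvalues_uniform(self):
        """Independent observed/predicted pairs: the p-value must be
        uniform on (0,1) -- Kolmogorov-Smirnov over 500 simulations."""
        rng = np.random.default_rng(2024)
        pvals = [
            association_test(rng.normal(size=1000), rng.normal(size=1000))
            for _ in range(500)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            association_test(np.full(6, 1.0), np.arange(6.0))


def _signed_rank_exact_p(diff):
    """Exhaustive two-sided signed-rank p-value over all sign patterns."""
    d = np.asarray(diff, float)
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    ws = np.asarray(ws)
    total = 2**n
    p = 2 * min((ws <= w_obs).sum(), (ws >= w_obs).sum()) / total
    return min(p, 1.0)


class TestPairedModelTest:
    def test_identical_residuals_give_one(self):
        r = np.array([0.1, -0.2, 0.3, 0.4, -0.5, 0.6])
        assert paired_model_test(r, r) == 1.0

    def test_full_dominance_n6(self):
        a = np.array([0.1, 0.1, 0.1, 0.1, 0.1, 0.1])
        b = np.array([0.2, 0.3, 0.25, 0.4, 0.5, 0.21])
        assert paired_model_test(a, b) == pytest.approx(0.03125, abs=1e-12)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_exhaustive_enumeration_n8(self, trial):
        rng = np.random.default_rng(100 + trial)
        a = rng.normal(size=8)
        b = rng.normal(size=8)
        expected = _signed_rank_exact_p(np.abs(a) - np.abs(b))
        assert paired_model_test(a, b) == pytest.approx(expected, abs=1e-12)
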