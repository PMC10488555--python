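import numpy as np
import pytest
from scipy.optimize import fsolve

from scarspls.pls_core import loo_rmsecv
from scarspls.scars import (
    ScarsConfig,
    ars_sample,
    edf_retention_schedule,
    frequency_select,
    optimize_nm,
    run_scars_once,
    stability,
)
from scarspls.synthetic_data import make_planted_dataset


class TestStability:
    def test_known_moments(self):
        b = np.array([[1.0], [2.0], [3.0]])  # mean 2, sd 1
        assert stability(b).c[0] == pytest.approx(2.0)

    def test_constant_nonzero_column_is_infinitely_stable(self):
        b = np.tile([1.5, 0.0], (4, 1))
        c = stability(b).c
        assert np.isinf(c[0]) and c[1] == 0.0

    def test_matches_brute_force_moments(self):
        rng = np.random.default_rng(0)
        b = rng.standard_normal((5, 3))
        c = stability(b).c
        for j in range(3):
            col = b[:, j]
            sd = np.sqrt(np.sum((col - col.mean()) ** 2) / 4)
            assert c[j] == pytest.approx(abs(col.mean()) / sd, abs=1e-12)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            stability(np.ones((1, 3)))


class TestEdfSchedule:
    def test_two_iterations_endpoints(self):
        np.testing.assert_array_equal(edf_retention_schedule(2, 100), [100, 2])

    @pytest.mark.parametrize("N,p", [(5, 50), (20, 949), (100, 935), (3, 10)])
    def test_endpoints_and_monotonicity(self, N, p):
        sched = edf_retention_schedule(N, p)
        assert sched[0] == p and sched[-1] == 2
        assert np.all(np.diff(sched) <= 0) and np.all(sched >= 2)

    def test_matches_closed_form_solver(self):
        """Oracle: solve a*exp(-k)=1 and a*exp(-k*N)=2/p numerically and
        evaluate the schedule from the solved constants."""
        N, p = 50, 949

        def equations(v):
            log_a, k = v
            return [log_a - k - 0.0, log_a - k * N - np.log(2.0 / p)]

        log_a, k = fsolve(equations, [0.1, 0.1])
        i = np.arange(1, N + 1)
        expected = np.minimum.accumulate(
            np.clip(np.rint(np.exp(log_a - k * i) * p).astype(int), 2, p)
        )
        np.testing.assert_array_equal(edf_retention_schedule(N, p), expected)


class TestArsSample:
    def test_lone_positive_weight_always_selected(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert ars_sample(np.array([1.0, 0.0, 0.0]), 1, rng).tolist() == [0]

    def test_equal_weights_full_count_returns_all(self):
        rng = np.random.default_rng(0)
        out = ars_sample(np.ones(7), 7, rng)
        np.testing.assert_array_equal(out, np.arange(7))

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            ars_sample(np.zeros(4), 2, np.random.default_rng(0))

    def test_infinite_weights_selected_first(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            out = ars_sample(np.array([1.0, np.inf, 1.0, np.inf]), 2, rng)
            np.testing.assert_array_equal(out, [1, 3])

    def test_inclusion_probability_of_dominant_weight(self):
        """Sequential sampling without replacement of 2 from weights
        [10,1,1,1]: P(index 0 included) = 1 - (3/13)(2/12) ~ 0.962."""
        rng = np.random.default_rng(123)
        w = np.array([10.0, 1.0, 1.0, 1.0])
        hits = sum(0 in ars_sample(w, 2, rng) for _ in range(10_000))
        assert hits / 10_000 >= 0.95

    def test_with_replacement_can_return_fewer(self):
        rng = np.random.default_rng(5)
        sizes = {ars_sample(np.ones(10), 6, rng, with_replacement=True).size for _ in range(50)}
        assert max(sizes) <= 6 and min(sizes) < 6


@pytest.fixture(scope="module")
def planted():
    return make_planted_dataset(n_cal=40, n_pred=20, n_variables=30, n_informative=3, seed=2)


class TestRunScarsOnce:
    def test_subset_sizes_follow_schedule(self, planted):
        X, y, _, _, _ = planted
        cfg = ScarsConfig(max_lvs=5)
        res = run_scars_once(X, y, cfg, np.random.default_rng(0), N=8, M=5)
        sizes = [s.size for s in res.subsets]
        np.testing.assert_array_equal(sizes, edf_retention_schedule(8, 30))

    def test_trace_minimum_not_worse_than_full_spectrum(self, planted):
        X, y, _, _, _ = planted
        cfg = ScarsConfig(max_lvs=5)
        res = run_scars_once(X, y, cfg, np.random.default_rng(1), N=8, M=5)
        full = loo_rmsecv(X, y, max_lvs=5).best_rmsecv
        assert res.best_rmsecv <= full + 1e-12
        assert res.best_rmsecv == pytest.approx(res.rmsecv_trace.min())

    def test_single_iteration_returns_full_spectrum_result(self, planted):
        X, y, _, _, _ = planted
        cfg = ScarsConfig(max_lvs=5)
        res = run_scars_once(X, y, cfg, np.random.default_rng(0), N=1, M=5)
        assert res.best_subset.size == X.shape[1]

    def test_reproducible_given_seed(self, planted):
        X, y, _, _, _ = planted
        cfg = ScarsConfig(max_lvs=5)
        a = run_scars_once(X, y, cfg, np.random.default_rng(9), N=6, M=4)
        b = run_scars_once(X, y, cfg, np.random.default_rng(9), N=6, M=4)
        np.testing.assert_array_equal(a.best_subset, b.best_subset)
        np.testing.assert_allclose(a.rmsecv_trace, b.rmsecv_trace)

    def test_best_subset_contains_planted_signal(self, planted):
        X, y, _, _, idx = planted
        cfg = ScarsConfig(max_lvs=5)
        hits = 0
        for seed in range(3):
            res = run_scars_once(X, y, cfg, np.random.default_rng(seed), N=20, M=10)
            hits += set(idx.tolist()) <= set(res.best_subset.tolist())
        assert hits >= 2


class TestOptimizeNm:
    def test_returns_pair_from_grid_and_is_deterministic(self, planted):
        X, y, _, _, _ = planted
        cfg = ScarsConfig(nm_grid=(5, 8), nm_repetitions=2, max_lvs=4)
        a = optimize_nm(X, y, cfg, np.random.default_rng(3))
        b = optimize_nm(X, y, cfg, np.random.default_rng(3))
        assert a.best in {(n, m) for n in (5, 8) for m in (5, 8)}
        assert a.best == b.best and a.mrmsecv == b.mrmsecv

    def test_best_pair_attains_table_minimum(self, planted):
        X, y, _, _, _ = planted
        cfg = ScarsConfig(nm_grid=(5, 8), nm_repetitions=2, max_lvs=4)
        res = optimize_nm(X, y, cfg, np.random.default_rng(4))
        assert res.mrmsecv[res.best] == min(res.mrmsecv.values())


class TestFrequencySelect:
    def test_counts_bounded_and_levels_nested(self, planted):
        X, y, Xp, yp, _ = planted
        cfg = ScarsConfig(final_runs=6, max_lvs=5)
        table, _ = frequency_select(X, y, Xp, yp, 10, 5, cfg, np.random.default_rng(0))
        assert table.counts.max() <= cfg.final_runs
        previous = None
        for level in table.frequency_levels:
            current = set(np.flatnonzero(table.counts >= level).tolist())
            if previous is not None:
                assert current >= previous
            previous = current

    def test_recovers_planted_variables(self, planted):
        X, y, Xp, yp, idx = planted
        cfg = ScarsConfig(final_runs=8, max_lvs=5)
        table, model = frequency_select(X, y, Xp, yp, 15, 8, cfg, np.random.default_rng(1))
        assert set(idx.tolist()) <= set(table.chosen_variables.tolist())
        assert model.n_variables == table.chosen_variables.size
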