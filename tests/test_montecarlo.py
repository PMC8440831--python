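"""Deviation pooling, KDE sampling, convergence, bands, sensitivities."""

import numpy as np
import pytest

from spinemc.model import N_PARAMETERS, ParameterVector, apply_perturbation
from spinemc.montecarlo import (
    GROUP_KEYS,
    KDESampler,
    MonteCarloSettings,
    check_convergence,
    confidence_bands,
    fit_kde,
    pool_deviations,
    run_monte_carlo,
    sample_parameter_vector,
    sensitivity_factors,
    summarize_deviations,
    t_sigma_max_stats,
)
from spinemc.synth import OperatorVariabilitySpec, emulate_operators


def brute_force_first_converged_n(history, window_frac=0.1, tol=0.02,
                                  min_iter=2, abs_floor=0.01,
                                  floor_below=0.5):
    """Literal recomputation of every running statistic with python loops."""
    h = np.atleast_2d(np.asarray(history, dtype=float).T).T
    N, k = h.shape
    for n in range(max(min_iter, 2), N + 1):
        w = max(2, int(np.ceil(window_frac * n)))
        if n - w + 1 < 2:
            continue
        ok = True
        for stat in (np.mean, lambda a: np.std(a, ddof=1)):
            ref = np.array([stat(h[:n, c]) for c in range(k)])
            for i in range(n - w + 1, n + 1):
                if i < 2:
                    ok = False
                    break
                run = np.array([stat(h[:i, c]) for c in range(k)])
                for c in range(k):
                    t = abs_floor if abs(ref[c]) < floor_below \
                        else tol * abs(ref[c])
                    if abs(run[c] - ref[c]) > t:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            return n
    return None


class TestPoolDeviations:
    def test_identical_operators_pool_to_zero(self, model):
        ops = [model.copy(), model.copy(), model.copy()]
        pool = pool_deviations([ops])
        for key in GROUP_KEYS:
            np.testing.assert_allclose(pool.group(*key), 0.0, atol=1e-9)

    def test_group_sizes_match_counting(self, operator_study):
        """3 subjects x 3 operators: the marker-position-x group pools
        28 markers x 3 operators x 3 subjects = 252 samples."""
        subjects, baselines = operator_study
        pool = pool_deviations(subjects, baselines)
        assert pool.group("marker", "position", "x").size == 252
        assert pool.group("body", "position", "y").size == 18 * 3 * 3
        assert pool.group("joint", "orientation", "z").size == 17 * 3 * 3

    def test_position_deviations_mean_center_per_subject(self, operator_study):
        """The arithmetic-mean baseline centres each position slot, so the
        three operators' deviations sum to ~0 within each subject."""
        subjects, baselines = operator_study
        from spinemc.model import model_to_vector
        for ops, base in zip(subjects, baselines):
            vecs = np.stack([model_to_vector(o, base).values for o in ops])
            pos_slots = np.r_[0:84, 84:138, 192:243]  # marker/body/joint pos
            np.testing.assert_allclose(vecs[:, pos_slots].sum(axis=0), 0.0,
                                       atol=1e-9)


class TestSummarizeDeviations:
    def test_zero_pool_summarizes_to_zero(self, model):
        pool = pool_deviations([[model.copy(), model.copy()]])
        s = summarize_deviations(pool)
        np.testing.assert_allclose(s.table["median"], 0.0, atol=1e-9)
        np.testing.assert_allclose(s.table["max"], 0.0, atol=1e-9)
        assert s.marker_distance_median == pytest.approx(0.0, abs=1e-9)

    def test_single_sample_group_median_equals_max(self):
        from spinemc.montecarlo import DeviationPool
        groups = {k: np.array([2.0]) for k in GROUP_KEYS}
        pool = DeviationPool(groups, np.array([[2.0, 0.0, 0.0]]), 1, 1)
        s = summarize_deviations(pool)
        assert (s.table["median"] == 2.0).all()
        assert (s.table["max"] == 2.0).all()

    def test_default_spreads_land_at_reported_magnitudes(self,
                                                         operator_study):
        subjects, baselines = operator_study
        s = summarize_deviations(pool_deviations(subjects, baselines))
        t = s.table.set_index(["component", "parameter"]).sort_index()
        med = t.loc[("marker", "position"), "median"]
        assert ((med > 0.05) & (med < 0.3)).all()


class TestKDE:
    def test_moment_recovery_from_normal_samples(self, rng):
        samples = rng.normal(0.0, 1.0, size=500)
        s = KDESampler(samples)
        draws = s.sample(np.random.default_rng(1), 10_000)
        assert abs(draws.mean()) < 0.1
        assert abs(draws.std() - 1.0) < 0.15

    def test_degenerate_identical_samples(self):
        s = KDESampler(np.full(10, 3.5))
        draws = s.sample(np.random.default_rng(0), 100)
        np.testing.assert_array_equal(draws, 3.5)
        s_eps = KDESampler(np.full(10, 3.5), bandwidth_floor=0.01)
        draws = s_eps.sample(np.random.default_rng(0), 1000)
        assert 0.0 < np.abs(draws - 3.5).max() < 0.06

    def test_pdf_integrates_to_one(self, rng):
        s = KDESampler(rng.normal(2.0, 0.5, size=50))
        x = np.linspace(-3, 7, 4001)
        integral = np.trapezoid(s.pdf(x), x)
        assert integral == pytest.approx(1.0, abs=1e-3)

    def test_group_samplers_are_isolated(self, operator_study, model):
        """Drawing a parameter vector perturbs each entry only from its own
        group's sampler: zeroing one group's pool zeroes exactly its slots."""
        subjects, baselines = operator_study
        pool = pool_deviations(subjects, baselines)
        pool.groups[("joint", "orientation", "y")] = np.zeros(20)
        dists = fit_kde(pool)
        vec = sample_parameter_vector(dists, model.marker_names,
                                      np.random.default_rng(0))
        layout = ParameterVector.layout(model.marker_names)
        sel = ((layout.component == "joint") &
               (layout.parameter == "orientation") &
               (layout.direction == "y")).to_numpy()
        assert np.all(vec.values[sel] == 0.0)
        assert np.all(vec.values[~sel] != 0.0)

    def test_too_few_samples_raises_helpful_error(self):
        with pytest.raises(ValueError, match="OperatorVariabilitySpec"):
            KDESampler(np.arange(3.0))


class TestCheckConvergence:
    def test_constant_history_converges_at_minimum_checkable_n(self):
        h = np.ones((300, 3))
        assert check_convergence(h, min_iter=100) == 100

    def test_step_change_inside_window_defers_convergence(self):
        h = np.ones((120, 1)) * 10.0
        h[115:] = 20.0
        # candidates whose final 10% window straddles the step never converge
        assert check_convergence(h, min_iter=116) is None
        # ... while the constant prefix before the step does
        assert check_convergence(h[:110], min_iter=100) == 100

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_bruteforce_on_random_histories(self, seed):
        rng = np.random.default_rng(seed)
        h = rng.normal(1.0, 0.3, size=(rng.integers(30, 120), 2))
        got = check_convergence(h, min_iter=5)
        want = brute_force_first_converged_n(h, min_iter=5)
        assert got == want

    def test_short_history_returns_none(self):
        assert check_convergence(np.ones((5, 2)), min_iter=100) is None


class TestConfidenceBands:
    def test_identical_curves_give_zero_width_bands(self):
        curve = np.sin(np.linspace(0, 1, 100))[None, None, :]
        curves = np.repeat(np.repeat(curve, 30, axis=0), 51, axis=1)
        bands = confidence_bands(curves)
        np.testing.assert_allclose(bands[..., 0], bands[..., 1], atol=1e-12)
        np.testing.assert_allclose(bands[..., 0], curves[0], atol=1e-12)

    def test_uniform_scaling_matches_order_statistics(self, rng):
        """Curves c * const with c ~ U(0,1): pointwise percentiles are the
        order statistics of the uniform sample, ~[0.05, 0.95] * const."""
        c = rng.uniform(0, 1, size=1000)
        const = 4.0 * np.ones((1, 100))
        curves = (c[:, None, None] * const[None]).repeat(1, axis=1)
        bands = confidence_bands(curves)
        assert bands[..., 0].mean() == pytest.approx(0.05 * 4.0, abs=0.1)
        assert bands[..., 1].mean() == pytest.approx(0.95 * 4.0, abs=0.1)

    def test_pointwise_coverage_is_at_least_ninety_percent(self, rng):
        curves = rng.normal(size=(200, 5, 100))
        bands = confidence_bands(curves)
        inside = ((curves >= bands[None, ..., 0]) &
                  (curves <= bands[None, ..., 1])).mean(axis=0)
        assert inside.min() >= 0.9 - 2.0 / 200
        assert inside.max() <= 1.0


class TestTSigmaMax:
    def test_constant_variance_ties_break_to_earliest_frame(self):
        rng = np.random.default_rng(0)
        sign = rng.choice([-1.0, 1.0], size=(40, 1, 1))
        curves = np.ones((40, 3, 100)) * sign
        stats = t_sigma_max_stats(curves)
        assert (stats["t_sigma_max"] == 0).all()

    def test_inflated_noise_at_frame_60_is_found(self, rng):
        curves = rng.normal(0, 0.1, size=(50, 4, 100))
        curves[:, 2, 60] += rng.normal(0, 5.0, size=50)
        stats = t_sigma_max_stats(curves)
        assert stats.loc[2, "t_sigma_max"] == 60

    def test_symmetric_two_curve_set(self):
        d = 3.0
        curves = np.stack([np.full((1, 100), d), np.full((1, 100), -d),
                           np.full((1, 100), d), np.full((1, 100), -d),
                           np.zeros((1, 100))])
        stats = t_sigma_max_stats(curves)
        assert stats.loc[0, "median"] == 0.0
        assert stats.loc[0, "min"] == -d
        assert stats.loc[0, "max"] == d


class TestSensitivityFactors:
    def test_rigged_output_has_unit_correlation(self, rng):
        draws = rng.normal(size=(100, N_PARAMETERS))
        draws[:, 3] = rng.uniform(1.0, 2.0, size=100)  # positive draws
        curves = np.zeros((100, 51, 100))
        curves[:, 7, :] = draws[:, [3]]   # DOF 7 mirrors parameter 3
        r, defined = sensitivity_factors(draws, curves)
        assert r[3, 7] == pytest.approx(1.0, abs=1e-9)
        assert defined[3, 7]

    def test_independent_draws_give_near_zero_correlations(self, rng):
        draws = rng.normal(size=(2000, N_PARAMETERS))
        curves = np.abs(rng.normal(size=(2000, 51, 1))).repeat(2, axis=2)
        r, _ = sensitivity_factors(draws, curves)
        assert (np.abs(r) < 0.1).mean() >= 0.99

    def test_zero_variance_column_flagged_as_zero(self, rng):
        draws = rng.normal(size=(50, N_PARAMETERS))
        draws[:, 5] = 2.0
        curves = rng.normal(size=(50, 51, 100))
        r, defined = sensitivity_factors(draws, curves)
        assert np.all(r[5] == 0.0)
        assert not defined[5].any()


class TestRunMonteCarlo:
    def test_degenerate_distributions_give_zero_bands_and_min_n(
            self, mc_inputs, model):
        """All samplers exactly at 0: every relative curve vanishes, bands
        have zero width and the run converges at the minimum allowed n."""
        base, trial, _ = mc_inputs
        ops = [base.copy(), base.copy(), base.copy()]
        pool = pool_deviations([ops], [base])
        dists = fit_kde(pool)
        settings = MonteCarloSettings(max_iter=40, min_iter=25, seed=1)
        res = run_monte_carlo(base, dists, trial, settings)
        assert res.converged_n == 25
        assert np.abs(res.relative_curves).max() < 1e-9
        bands = res.bands()
        np.testing.assert_allclose(bands[..., 1] - bands[..., 0], 0.0,
                                   atol=1e-12)
        r, defined = res.sensitivity(base.marker_names)
        assert np.all(r == 0.0)
        assert not defined.any()

    def test_same_seed_is_bit_identical(self, mc_inputs, operator_study):
        subjects, baselines = operator_study
        base, trial, _ = mc_inputs
        pool = pool_deviations(subjects, baselines)
        dists = fit_kde(pool)
        settings = MonteCarloSettings(max_iter=8, min_iter=1000, seed=7)
        a = run_monte_carlo(base, dists, trial, settings)
        b = run_monte_carlo(base, dists, trial, settings)
        np.testing.assert_array_equal(a.draws, b.draws)
        np.testing.assert_array_equal(a.relative_curves, b.relative_curves)
        assert a.n_iterations == b.n_iterations == 8
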