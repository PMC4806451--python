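"""HMM core: oracle equivalence, EM behaviour, state resolution, decoding.

The primary oracle is exhaustive enumeration of all 2^B state paths using
the joint-likelihood product; the scaled forward/backward recursions must
reproduce its likelihood and marginals.  hmmlearn's independently-coded
forward pass serves as a second cross-check of the likelihood.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from chipdomains import ObservationSeries, TwoStateHMM
from chipdomains.hmm import (
    DegenerateSeriesError,
    FitResult,
    GaussianEmission,
    HMMParams,
    average_params,
    decode,
    em_fit,
    fit_chromosome,
    forward_backward,
    init_params,
    log_forward,
    resolve_enriched_state,
)
from chipdomains.simulate import default_generating_params, simulate_observations


def make_params(means=(0.0, 5.0), sds=(1.0, 1.0), self_p=0.9, prior=(0.5, 0.5)):
    return HMMParams(
        prior=np.array(prior),
        transitions=np.array([[self_p, 1 - self_p], [1 - self_p, self_p]]),
        emissions=(GaussianEmission(means[0], sds[0]), GaussianEmission(means[1], sds[1])),
    )


def series_of(values):
    values = np.asarray(values, dtype=float)
    return ObservationSeries("t", values, np.arange(values.size))


def brute_force(values, params):
    """Joint-likelihood sum over all 2^B paths: total and per-bin marginals."""
    B = len(values)
    pdf = np.column_stack(
        [norm.pdf(values, e.mean, e.sd) for e in params.emissions]
    )
    total = 0.0
    marginal = np.zeros((B, 2))
    for path in itertools.product((0, 1), repeat=B):
        p = params.prior[path[0]] * pdf[0, path[0]]
        for b in range(1, B):
            p *= params.transitions[path[b - 1], path[b]] * pdf[b, path[b]]
        total += p
        for b, s in enumerate(path):
            marginal[b, s] += p
    return math.log(total), marginal / total


ORACLE_CASES = [
    ((0.0, 5.0), (1.0, 1.0), 0.9, [0.0, 0.0, 5.0, 5.0, 0.0, 5.0]),
    ((0.0, 5.0), (1.0, 1.0), 0.9, [1.2, -0.3, 4.8, 0.1, 2.5, 5.5, 4.9, 0.2]),
    ((0.0, 15.0), (5.0, 5.0), 0.95, [2.0, 18.0, -4.0]),
    ((-2.0, 3.0), (0.5, 2.0), 0.7, [0.3, 0.3, 0.3, -2.1, 2.9]),
]


class TestOracleEquivalence:
    def test_single_bin_closed_form(self):
        params = make_params()
        series = series_of([1.3])
        loglik, alpha, scales = log_forward(series, params)
        expected = math.log(
            0.5 * norm.pdf(1.3, 0, 1) + 0.5 * norm.pdf(1.3, 5, 1)
        )
        assert loglik == pytest.approx(expected, abs=1e-12)
        post = forward_backward(series, params)
        np.testing.assert_allclose(post[0], alpha[0], atol=1e-12)

    @pytest.mark.parametrize("means, sds, self_p, values", ORACLE_CASES)
    def test_forward_matches_path_enumeration(self, means, sds, self_p, values):
        params = make_params(means, sds, self_p)
        expected_ll, _ = brute_force(values, params)
        loglik, _, scales = log_forward(series_of(values), params)
        assert loglik == pytest.approx(expected_ll, abs=1e-8)
        assert loglik == pytest.approx(float(np.sum(scales)), abs=1e-10)

    @pytest.mark.parametrize("means, sds, self_p, values", ORACLE_CASES)
    def test_posteriors_match_path_enumeration(self, means, sds, self_p, values):
        params = make_params(means, sds, self_p)
        _, expected = brute_force(values, params)
        post = forward_backward(series_of(values), params)
        np.testing.assert_allclose(post, expected, atol=1e-10)

    def test_decode_matches_marginal_argmax(self):
        params = make_params((0.0, 5.0), (1.0, 1.0), 0.8)
        values = [0.1, 4.2, 4.8, 0.0, 2.6, 5.1]
        _, marg = brute_force(values, params)
        track = decode(series_of(values), params)
        np.testing.assert_array_equal(track.state, marg.argmax(axis=1))
        np.testing.assert_allclose(track.posterior, marg.max(axis=1), atol=1e-10)

    def test_scaling_observations_and_sds_shifts_loglik(self):
        params = make_params((0.0, 5.0), (1.0, 2.0))
        values = np.array([0.3, 4.4, -1.0, 6.2])
        c = 3.0
        scaled = HMMParams(
            params.prior,
            params.transitions,
            (
                GaussianEmission(0.0 * c, 1.0 * c),
                GaussianEmission(5.0 * c, 2.0 * c),
            ),
        )
        ll, _, _ = log_forward(series_of(values), params)
        ll_scaled, _, _ = log_forward(series_of(values * c), scaled)
        assert ll_scaled == pytest.approx(ll - len(values) * math.log(c), abs=1e-10)

    def test_loglik_matches_hmmlearn(self):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        params = make_params((0.0, 15.0), (5.0, 5.0), 0.95)
        series, _ = simulate_observations(default_generating_params(), 400, seed=9)
        model = hmmlearn.GaussianHMM(n_components=2, covariance_type="diag", init_params="")
        model.startprob_ = params.prior
        model.transmat_ = params.transitions
        model.means_ = np.array([[0.0], [15.0]])
        model.covars_ = np.array([[25.0], [25.0]])
        expected = model.score(series.values.reshape(-1, 1))
        loglik, _, _ = log_forward(series, params)
        assert loglik == pytest.approx(expected, rel=1e-10)

    @given(st.lists(st.floats(-20, 40, allow_nan=False), min_size=1, max_size=30))
    @settings(max_examples=60, deadline=None)
    def test_posterior_rows_sum_to_one(self, values):
        params = make_params((0.0, 15.0), (5.0, 4.0), 0.95)
        post = forward_backward(series_of(values), params)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)
        assert (post >= 0).all()

    def test_identical_emissions_make_posteriors_data_independent(self):
        params = make_params((2.0, 2.0), (3.0, 3.0), 0.8, prior=(0.7, 0.3))
        a = forward_backward(series_of([0.0, 10.0, -5.0]), params)
        b = forward_backward(series_of([2.0, 2.0, 2.0]), params)
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestInitParams:
    def test_enriched_mean_is_three_times_empirical(self):
        rng = np.random.default_rng(2)
        values = rng.normal(2.0, 5.0, 50_000)
        params = init_params(series_of(values))
        mean, sd = values.mean(), values.std()
        assert params.emissions[1].mean == pytest.approx(3 * mean)
        assert params.emissions[0].mean == pytest.approx(mean)
        assert params.emissions[0].sd == pytest.approx(sd)
        assert params.emissions[1].sd == pytest.approx(sd)
        np.testing.assert_allclose(params.prior, [0.5, 0.5])

    def test_zero_variance_is_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            init_params(series_of([3.0, 3.0, 3.0]))
        with pytest.raises(DegenerateSeriesError):
            init_params(series_of([3.0]))

    def test_zero_mean_leaves_states_coincident(self):
        values = np.array([-1.0, 1.0, -2.0, 2.0])
        params = init_params(series_of(values))
        assert params.emissions[0].mean == params.emissions[1].mean == 0.0


class TestEMFit:
    def test_recovers_generating_parameters(self):
        truth = default_generating_params()
        series, _ = simulate_observations(truth, 5000, seed=3)
        result = em_fit(series, init_params(series))
        assert result.converged
        p = result.params
        if p.emissions[0].mean > p.emissions[1].mean:
            p = p.swap_states()  # equal-sd truth: align to it by mean
        assert p.emissions[0].mean == pytest.approx(0.0, abs=1.0)
        assert p.emissions[1].mean == pytest.approx(15.0, abs=1.0)

    def test_loglik_trace_non_decreasing(self):
        for seed in (0, 1, 2):
            series, _ = simulate_observations(default_generating_params(), 800, seed=seed)
            result = em_fit(series, init_params(series))
            diffs = np.diff(result.loglik_trace)
            assert (diffs >= -1e-8).all()

    def test_restart_from_optimum_converges_immediately(self):
        series, _ = simulate_observations(default_generating_params(), 1000, seed=4)
        first = em_fit(series, init_params(series))
        assert first.converged
        again = em_fit(series, first.params)
        assert again.converged
        assert again.n_iterations <= 2

    def test_too_short_series_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            em_fit(series_of([1.0]), default_generating_params())


class TestFitChromosome:
    def test_well_separated_series_converges(self):
        series, _ = simulate_observations(default_generating_params(), 2000, seed=5)
        assert fit_chromosome(series).converged

    def test_constant_series_flagged_not_raised(self):
        result = fit_chromosome(series_of(np.zeros(100)))
        assert not result.converged

    def test_adversarial_series_exercises_retry_without_crashing(self):
        # one extreme outlier over near-constant jitter: collapse-prone
        rng = np.random.default_rng(6)
        values = np.concatenate([rng.normal(0, 1e-3, 200), [500.0]])
        result = fit_chromosome(series_of(values), seed=1)
        assert isinstance(result.converged, bool)

    def test_fit_is_independent_of_other_chromosomes(self):
        a, _ = simulate_observations(default_generating_params(), 600, seed=7)
        b, _ = simulate_observations(default_generating_params(), 600, seed=8)
        alone = fit_chromosome(a)
        after_other = fit_chromosome(b) and fit_chromosome(a)
        np.testing.assert_array_equal(alone.loglik_trace, after_other.loglik_trace)


class TestStateResolution:
    @pytest.mark.parametrize(
        "sds, means, expected",
        [
            ((5.0, 12.0), (0.0, 1.0), 1),
            ((12.0, 5.0), (1.0, 0.0), 0),
            ((5.0, 5.0), (0.0, 8.0), 1),
        ],
    )
    def test_highest_variance_wins(self, sds, means, expected):
        params = make_params(means, sds)
        assert resolve_enriched_state(params) == expected

    def test_average_params_pairs_enriched_with_enriched(self):
        a = make_params((0.0, 10.0), (2.0, 6.0))
        b = make_params((14.0, 0.0), (6.0, 2.0))  # label-inverted twin
        avg = average_params(
            [FitResult(a, True, np.array([0.0])), FitResult(b, True, np.array([0.0]))]
        )
        assert avg.emissions[1].mean == pytest.approx(12.0)
        assert avg.emissions[0].mean == pytest.approx(0.0)

    def test_average_of_single_result_is_identity(self):
        p = make_params((0.0, 10.0), (2.0, 6.0))
        avg = average_params([FitResult(p, True, np.array([0.0]))])
        np.testing.assert_allclose(avg.prior, p.prior)
        np.testing.assert_allclose(avg.transitions, p.transitions)
        assert avg.emissions[1].mean == 10.0

    def test_no_converged_results_is_an_error(self):
        p = make_params()
        with pytest.raises(RuntimeError, match="no chromosome"):
            average_params([FitResult(p, False, np.array([]))])


class TestDecode:
    def test_posterior_of_assigned_state_is_at_least_half(self):
        params = make_params((0.0, 15.0), (5.0, 5.0), 0.95)
        series, _ = simulate_observations(params, 500, seed=10)
        track = decode(series, params)
        assert (track.posterior >= 0.5).all()
        assert (track.posterior <= 1.0).all()

    def test_exact_tie_goes_to_depleted(self):
        # identical emissions, symmetric prior/transitions: posterior exactly 0.5
        params = make_params((1.0, 1.0), (2.0, 2.0), 0.5)
        track = decode(series_of([0.0, 3.0]), params)
        assert (track.state == 0).all()
        np.testing.assert_allclose(track.posterior, 0.5, atol=1e-12)

    def test_label_swap_invariance_of_final_calls(self):
        """Fitting from swapped initial labels yields identical enriched calls."""
        series, _ = simulate_observations(default_generating_params(), 2000, seed=12)
        init = init_params(series)
        straight = em_fit(series, init)
        swapped = em_fit(series, init.swap_states())
        assert straight.converged and swapped.converged
        track_a = decode(series, straight.params)
        track_b = decode(series, swapped.params)
        np.testing.assert_array_equal(track_a.state, track_b.state)
        np.testing.assert_allclose(track_a.posterior, track_b.posterior, atol=1e-6)


class TestModelSurface:
    def test_fit_results_carry_estimates_and_summary(self):
        series, _ = simulate_observations(default_generating_params(), 1500, seed=13)
        res = TwoStateHMM(series).fit()
        assert res.converged
        assert res.llf == pytest.approx(res.loglik_trace[-1])
        text = res.summary()
        assert "enriched" in text and "depleted" in text
        assert res.posteriors().shape == (1500, 2)

    def test_plain_array_input_is_wrapped(self):
        res = TwoStateHMM([0.1, -0.2, 14.0, 15.0, 0.3, 14.5]).fit(max_iter=50)
        assert res.decode().state.shape == (6,)
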