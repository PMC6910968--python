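"""Distribution construction, sampling correctness and the Monte Carlo engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from bioassess.uncertainty import (
    ConfigurationError,
    Distribution,
    MonteCarloError,
    ParameterDraw,
    ScenarioSpace,
    draw_parameters,
    make_conservative_triangular,
    run_monte_carlo,
    sample_scenarios,
    substream,
    triangular_cdf,
)


class TestDistribution:
    def test_invariant_violations_rejected(self):
        with pytest.raises(ConfigurationError):
            Distribution("triangular", (10, 5, 20))  # min > mode
        with pytest.raises(ConfigurationError):
            Distribution("uniform", (5, 5))
        with pytest.raises(ConfigurationError):
            Distribution("discrete", outcomes={"a": 0.6, "b": 0.6})
        with pytest.raises(ConfigurationError):
            Distribution("lognormal", (0, 1))

    def test_point_samples_exact_copies(self, rng):
        assert (Distribution("point", (7.0,)).sample(rng, 100) == 7.0).all()

    def test_uniform_stays_in_transport_range(self, rng):
        # transport distance spec: uniform between 100 and 400 km
        x = Distribution("uniform", (100, 400)).sample(rng, 10_000)
        assert x.min() >= 100 and x.max() <= 400

    def test_triangular_moments_match_closed_forms(self, rng):
        a, c, b = 5.0, 10.0, 20.0
        x = Distribution("triangular", (a, c, b)).sample(rng, 100_000)
        mean = (a + b + c) / 3
        var = (a**2 + b**2 + c**2 - a * b - a * c - b * c) / 18
        se = np.sqrt(var / x.size)
        assert abs(x.mean() - mean) < 3 * se
        assert abs(x.mean() - mean) < 0.05
        assert np.isclose(x.var(), var, rtol=0.05)

    def test_triangular_ks_against_analytic_cdf(self, rng):
        a, c, b = 5.0, 10.0, 20.0
        x = Distribution("triangular", (a, c, b)).sample(rng, 10_000)
        ks = stats.kstest(x, lambda q: triangular_cdf(q, a, c, b)).statistic
        critical_1pct = 1.6276 / np.sqrt(x.size)
        assert ks < critical_1pct


class TestConservativeTriangular:
    def test_half_double_rule(self):
        d = make_conservative_triangular(10.0)
        assert d.kind == "triangular" and d.params == (5.0, 10.0, 20.0)

    def test_negative_value_swaps_bounds(self):
        d = make_conservative_triangular(-10.0)
        assert d.params == (-20.0, -10.0, -5.0)

    def test_zero_degenerates_to_point(self):
        d = make_conservative_triangular(0.0)
        assert d.kind == "point" and d.params == (0.0,)

    @given(st.floats(min_value=1e-6, max_value=1e6, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_mode_is_published_value_and_bounds_bracket(self, v):
        d = make_conservative_triangular(v)
        a, c, b = d.params
        assert a <= c <= b and c == v and np.isclose(a, v / 2) and np.isclose(b, 2 * v)


class TestScenarios:
    def test_single_outcome_axis_always_that_outcome(self):
        space = ScenarioSpace({"x": Distribution("discrete", outcomes={"only": 1.0})})
        for i in range(10):
            assert sample_scenarios(space, seed=0, iteration=i) == {"x": "only"}

    def test_equiprobable_frequencies_converge(self):
        space = ScenarioSpace(
            {"x": Distribution("discrete", outcomes={"a": 0.5, "b": 0.5})})
        picks = [sample_scenarios(space, seed=3, iteration=i)["x"]
                 for i in range(10_000)]
        freq = picks.count("a") / len(picks)
        assert 0.48 <= freq <= 0.52

    def test_four_feedstock_axis(self, bundle):
        outcomes = bundle.space.axes["feedstock"].outcomes
        assert set(outcomes) == {"corn-stover-US", "corn-starch-US",
                                 "sugar-beet-FR", "sugarcane-BR"}

    def test_non_discrete_axis_rejected(self):
        with pytest.raises(ConfigurationError):
            ScenarioSpace({"x": Distribution("uniform", (0, 1))})


class TestMonteCarlo:
    PARAMS = {"u": Distribution("uniform", (0.0, 1.0))}

    def test_constant_model_summaries(self):
        res = run_monte_carlo(lambda d: 3.0, {}, n_iterations=50, seed=0)
        s = res.summaries["output"]
        assert s["mean"] == s["p2.5"] == s["p97.5"] == 3.0

    def test_identity_on_uniform_mean(self):
        res = run_monte_carlo(lambda d: d["u"], self.PARAMS,
                              n_iterations=10_000, seed=1)
        assert 0.49 < res.summaries["output"]["mean"] < 0.51

    def test_default_iteration_count_is_ten_thousand(self):
        import inspect
        sig = inspect.signature(run_monte_carlo)
        assert sig.parameters["n_iterations"].default == 10_000

    def test_same_seed_bit_identical(self):
        r1 = run_monte_carlo(lambda d: d["u"], self.PARAMS, n_iterations=500, seed=7)
        r2 = run_monte_carlo(lambda d: d["u"], self.PARAMS, n_iterations=500, seed=7)
        assert (r1.samples["output"] == r2.samples["output"]).all()

    def test_truncation_reproduces_prefix(self):
        # counter-based substreams: first 1,000 of a 10,000-run are bit-exact
        long = run_monte_carlo(lambda d: d["u"], self.PARAMS,
                               n_iterations=10_000, seed=9)
        short = run_monte_carlo(lambda d: d["u"], self.PARAMS,
                                n_iterations=1_000, seed=9)
        assert (long.samples["output"][:1000] == short.samples["output"]).all()

    def test_substreams_order_independent(self):
        params = {"a": Distribution("uniform", (0, 1)),
                  "b": Distribution("uniform", (0, 1))}
        d1 = draw_parameters(params, ScenarioSpace({}), seed=4, iteration=0)
        d2 = draw_parameters(dict(reversed(params.items())), ScenarioSpace({}),
                             seed=4, iteration=0)
        assert d1.values == d2.values

    def test_failures_logged_then_abort_over_threshold(self):
        def flaky(draw: ParameterDraw) -> float:
            if draw["u"] < 0.5:
                raise RuntimeError("boom")
            return 1.0

        with pytest.raises(MonteCarloError):
            run_monte_carlo(flaky, self.PARAMS, n_iterations=200, seed=0)

    def test_summaries_bracket_mean(self):
        res = run_monte_carlo(lambda d: d["u"] ** 2, self.PARAMS,
                              n_iterations=2000, seed=2)
        s = res.summaries["output"]
        assert s["p2.5"] <= s["mean"] <= s["p97.5"]


@given(st.integers(min_value=0, max_value=2**31 - 1),
       st.integers(min_value=0, max_value=10_000))
@settings(max_examples=30, deadline=None)
def test_substream_determinism(seed, iteration):
    a = substream(seed, iteration, "x").random(4)
    b = substream(seed, iteration, "x").random(4)
    c = substream(seed, iteration, "y").random(4)
    assert (a == b).all() and not (a == c).all()
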