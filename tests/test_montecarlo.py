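"""Monte Carlo propagation, reproducibility and sensitivity ranking."""

import numpy as np
import pytest

from dietrisk.distributions import DistributionSpec
from dietrisk.montecarlo import (
    iman_conover,
    run_monte_carlo,
    sensitivity,
    simulate_from_metric_fit,
)
from dietrisk.risk import ReferenceValues

REFS = ReferenceValues()


def point(v):
    return DistributionSpec("point", (v,))


class TestDegenerateInputs:
    def test_point_mass_moe_equals_deterministic(self):
        sim = run_monte_carlo(
            {"tomato": point(0.3003)}, {"tomato": point(0.003)},
            REFS, "moe", n_iterations=1000, seed=1,
        )
        expected = 0.3 / (0.003 * 0.3003 / 71.5)
        assert sim.summary.mean == pytest.approx(expected, rel=1e-12)
        assert sim.summary.sd == pytest.approx(0.0, abs=1e-6)

    def test_point_mass_hi_matches_summed_hq(self):
        sim = run_monte_carlo(
            {"tomato": point(0.374188), "cucumber": point(0.203060)},
            {"tomato": point(0.003), "cucumber": point(0.003)},
            REFS, "hi", n_iterations=1000, seed=1,
        )
        assert round(sim.summary.mean, 2) == 0.24


class TestPropagation:
    def test_reproducible_bit_for_bit(self):
        specs = (
            {"tomato": DistributionSpec("beta_general", (2.0, 4.0, 0.05, 1.2))},
            {"tomato": DistributionSpec("triangular", (0.002, 0.002, 0.005))},
        )
        a = run_monte_carlo(*specs, REFS, "hq", n_iterations=2000, seed=9)
        b = run_monte_carlo(*specs, REFS, "hq", n_iterations=2000, seed=9)
        assert np.array_equal(a.draws, b.draws)
        assert a.summary == b.summary

    def test_moe_times_edi_is_hbgv_per_iteration(self):
        sim = run_monte_carlo(
            {"tomato": DistributionSpec("triangular", (0.1, 0.3, 0.6))},
            {"tomato": DistributionSpec("triangular", (0.002, 0.003, 0.005))},
            REFS, "moe", n_iterations=5000, seed=2,
        )
        np.testing.assert_allclose(sim.draws * sim.edi_draws, REFS.hbgv_loael, rtol=1e-12)

    def test_moe_percentiles_match_quantile_transform(self):
        """With a point residue, MOE quantiles are the transformed
        consumption quantiles: q_p(MOE) = HBGV*BW / (c * q_{1-p}(C))."""
        cons = DistributionSpec("triangular", (0.1, 0.3, 0.6))
        sim = run_monte_carlo(
            {"tomato": cons}, {"tomato": point(0.003)},
            REFS, "moe", n_iterations=100_000, seed=3,
        )
        for p in (0.50, 0.75, 0.90, 0.95):
            analytic = REFS.hbgv_loael * REFS.bw / (0.003 * cons.ppf(1 - p))
            assert np.quantile(sim.draws, p) == pytest.approx(analytic, rel=0.02)

    def test_metric_horizon_compatibility_enforced(self):
        with pytest.raises(ValueError):
            run_monte_carlo({"t": point(1)}, {"t": point(1)}, REFS, "moe", horizon="acute")

    def test_mismatched_commodity_sets_rejected(self):
        with pytest.raises(ValueError):
            run_monte_carlo(
                {"tomato": point(1), "cucumber": point(1)},
                {"tomato": point(1)},
                REFS, "hi",
            )

    def test_single_commodity_metric_needs_one_commodity(self):
        with pytest.raises(ValueError):
            run_monte_carlo(
                {"a": point(1), "b": point(1)},
                {"a": point(1), "b": point(1)},
                REFS, "moe",
            )

    def test_empirical_inputs_bootstrap(self):
        data = np.array([0.1, 0.2, 0.3])
        sim = run_monte_carlo(
            {"tomato": data}, {"tomato": point(0.003)}, REFS, "hq",
            n_iterations=3000, seed=4,
        )
        drawn = set(np.round(sim.input_draws["tomato consumption"], 6))
        assert drawn <= {0.1, 0.2, 0.3}


class TestFitToMetricMode:
    def test_fitted_spec_and_draws_cover_metric_range(self):
        rng = np.random.default_rng(5)
        metric_values = rng.triangular(10_000, 20_000, 60_000, size=2_000)
        spec, sim = simulate_from_metric_fit(metric_values, "triangular",
                                             n_iterations=2_000, seed=5)
        assert spec.family == "triangular"
        assert sim.summary.mean == pytest.approx(metric_values.mean(), rel=0.05)


class TestSensitivity:
    def test_exact_dependence_ranks_first_with_correlation_one(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(size=2000)
        noise = rng.uniform(size=2000)
        ranked = sensitivity({"x": x, "noise": noise}, x)
        assert ranked[0][0] == "x"
        assert ranked[0][1] == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(7)
        n = 4000
        y = rng.uniform(size=n)
        ranked = dict(sensitivity({"noise": rng.uniform(size=n)}, y))
        assert abs(ranked["noise"]) < 3 / np.sqrt(n)

    def test_constant_input_gets_zero(self):
        y = np.arange(100.0)
        ranked = dict(sensitivity({"const": np.ones(100)}, y))
        assert ranked["const"] == 0.0


class TestImanConover:
    def test_induces_target_rank_correlation_preserving_marginals(self):
        rng = np.random.default_rng(8)
        cols = np.column_stack([rng.uniform(size=5000), rng.lognormal(size=5000)])
        target = np.array([[1.0, 0.7], [0.7, 1.0]])
        out = iman_conover(cols, target, rng)
        from scipy.stats import spearmanr
        assert spearmanr(out[:, 0], out[:, 1]).statistic == pytest.approx(0.7, abs=0.03)
        assert np.array_equal(np.sort(out[:, 0]), np.sort(cols[:, 0]))
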