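"""Procedure assessment: exact vs Monte-Carlo, the level-preservation metric."""

import itertools

import numpy as np
import pytest

from randeval.assess import (
    SimulationConfig,
    assess_exact,
    assess_procedure,
    metric_p_le,
    sensitivity_analysis,
    simulate_rejection_rate,
)
from randeval.bias import BiasModel, joint_tau
from randeval.design import power_two_sample_t
from randeval.nct import NoncentralityPair, noncentrality, rejection_probability
from randeval.procedures import ProcedureSpec, enumerate_sequences

NO_BIAS = BiasModel()


class TestNoBias:
    def test_exact_every_sequence_nominal(self):
        s = assess_exact(ProcedureSpec.pbr(2), 4, NO_BIAS, alpha=0.05)
        assert s.mean_omega == pytest.approx(0.05, abs=1e-9)
        assert s.p_le_alpha == 1.0
        assert s.quantiles["min"] == pytest.approx(0.05, abs=1e-9)
        assert s.quantiles["max"] == pytest.approx(0.05, abs=1e-9)

    def test_monte_carlo_nominal(self):
        s = assess_procedure(ProcedureSpec.bsd(3), 16, NO_BIAS, r=500, seed=1)
        assert s.mean_omega == pytest.approx(0.05, abs=1e-9)
        assert s.p_le_alpha == 1.0


class TestExactAgainstDirectSummation:
    def test_cr_selection_bias_direct_64_term_sum(self):
        """Exact assessment equals a hand-rolled sum over all 2^6 sequences."""
        n, eta, sigma, alpha = 6, 0.5, 1.0, 0.05
        bias = BiasModel(eta=eta, sigma=sigma)
        omegas, weights = [], []
        for bits in itertools.product((0, 1), repeat=n):
            t = np.asarray(bits)
            if t.sum() in (0, n):
                omegas.append(0.0)  # degenerate: test undefined, never rejects
            else:
                ne_before = np.concatenate(([0], np.cumsum(t)[:-1]))
                tau = eta * np.sign(2 * ne_before - np.arange(n))
                omegas.append(
                    rejection_probability(noncentrality(t, tau, sigma), alpha)
                )
            weights.append(1.0 / 2**n)
        expected_mean = float(np.dot(weights, omegas))
        expected_p = float(
            np.dot(weights, (np.asarray(omegas) <= alpha + 1e-9).astype(float))
        )
        s = assess_exact(ProcedureSpec.cr(), n, bias, alpha=alpha)
        assert s.mean_omega == pytest.approx(expected_mean, abs=1e-12)
        assert s.p_le_alpha == pytest.approx(expected_p, abs=1e-12)
        assert s.n_degenerate == 2

    def test_rar_linear_trend_uniform_over_balanced(self):
        n = 6
        bias = BiasModel(trend_kind="linear", theta=1.0, sigma=1.0)
        pairs = enumerate_sequences(ProcedureSpec.rar(), n)
        assert len(pairs) == 20
        trend = 1.0 * np.arange(1, n + 1) / n
        vals = [
            rejection_probability(noncentrality(s.assignments, trend, 1.0), 0.05)
            for s, _ in pairs
        ]
        s = assess_exact(ProcedureSpec.rar(), n, bias)
        assert s.mean_omega == pytest.approx(np.mean(vals), abs=1e-12)


class TestMonteCarloAgreesWithExact:
    @pytest.mark.parametrize(
        "spec",
        [ProcedureSpec.bsd(2), ProcedureSpec.ebc(0.7), ProcedureSpec.rar()],
        ids=lambda s: s.label,
    )
    def test_within_three_standard_errors(self, spec):
        n, r = 8, 30_000
        bias = BiasModel(eta=0.4, trend_kind="linear", theta=0.6, sigma=1.0)
        exact = assess_exact(spec, n, bias)
        mc = assess_procedure(spec, n, bias, r=r, seed=99)
        assert abs(mc.mean_omega - exact.mean_omega) <= 3 * mc.mean_omega_se
        p_se = np.sqrt(max(exact.p_le_alpha * (1 - exact.p_le_alpha), 1e-6) / r)
        assert abs(mc.p_le_alpha - exact.p_le_alpha) <= 3 * p_se + 1e-9

    def test_reported_binomial_se(self):
        s = assess_procedure(ProcedureSpec.cr(), 10, BiasModel(eta=0.3), r=2_000, seed=3)
        assert s.p_le_alpha_se == pytest.approx(
            np.sqrt(s.p_le_alpha * (1 - s.p_le_alpha) / 2_000)
        )


class TestRelabelingInvariance:
    def test_exact_summary_invariant_under_arm_swap(self):
        """Swapping E and C leaves mean omega and the metric unchanged."""
        from randeval.assess import sequence_omegas
        from randeval.sequences import as_matrix

        bias = BiasModel(eta=0.4, trend_kind="linear", theta=0.5, sigma=1.0)
        pairs = enumerate_sequences(ProcedureSpec.cr(), 6)
        tm = as_matrix([s for s, _ in pairs])
        w = np.array([p for _, p in pairs])
        om, _ = sequence_omegas(tm, bias, 0.05)
        om_swapped, _ = sequence_omegas(1 - tm, bias, 0.05)
        assert np.dot(w, om) == pytest.approx(np.dot(w, om_swapped), abs=1e-12)
        assert metric_p_le(om, 0.05, weights=w) == pytest.approx(
            metric_p_le(om_swapped, 0.05, weights=w), abs=1e-12
        )


class TestMetric:
    def test_boundary_inclusion(self):
        assert metric_p_le(np.full(10, 0.05), 0.05) == 1.0

    def test_even_split(self):
        assert metric_p_le(np.array([0.04, 0.06]), 0.05) == 0.5

    def test_weighted(self):
        assert metric_p_le(
            np.array([0.04, 0.06]), 0.05, weights=np.array([0.25, 0.75])
        ) == pytest.approx(0.25)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            metric_p_le(np.array([]), 0.05)


class TestSensitivity:
    def test_single_cell_equals_assess_procedure(self):
        spec = ProcedureSpec.bsd(2)
        grid = sensitivity_analysis(
            spec, 10, [0.3], [0.5], sigma=1.0, r=2_000, seed=17, trend_kind="linear"
        )
        direct = assess_procedure(
            spec, 10, BiasModel(eta=0.3, trend_kind="linear", theta=0.5, sigma=1.0),
            r=2_000, seed=17,
        )
        assert len(grid) == 1
        assert grid[0].mean_omega == direct.mean_omega
        assert grid[0].p_le_alpha == direct.p_le_alpha

    def test_no_bias_grid(self):
        grid = sensitivity_analysis(
            ProcedureSpec.cr(), 10, [0.0], [0.0], sigma=1.0, r=500, seed=2
        )
        assert grid[0].p_le_alpha == 1.0

    def test_cross_and_paired_shapes(self):
        kwargs = dict(sigma=1.0, r=200, seed=5, trend_kind="linear")
        crossed = sensitivity_analysis(ProcedureSpec.cr(), 8, [0.1, 0.2], [0.3, 0.4], **kwargs)
        paired = sensitivity_analysis(
            ProcedureSpec.cr(), 8, [0.1, 0.2], [0.3, 0.4], paired=True, **kwargs
        )
        assert len(crossed) == 4 and len(paired) == 2
        assert [(s.eta, s.theta) for s in paired] == [(0.1, 0.3), (0.2, 0.4)]


class TestSimulationOracle:
    def test_nominal_level_without_bias(self):
        n_sim = 200_000
        rate = simulate_rejection_rate(
            [1, 0] * 6, np.zeros(12), SimulationConfig(n_sim=n_sim, seed=8), 0.05
        )
        assert abs(rate - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / n_sim)

    def test_case_study_power(self):
        """Balanced two-arm design at the case-study effect has ~80% power."""
        n = 130
        t = np.tile([1, 0], n // 2)
        sim = SimulationConfig(mu_e=0.38, mu_c=0.0, sigma=0.765, n_sim=100_000, seed=13)
        rate = simulate_rejection_rate(t, np.zeros(n), sim, 0.05)
        expected = power_two_sample_t(65, 65, 0.38 / 0.765, 0.05)
        assert expected == pytest.approx(0.80, abs=0.01)
        assert abs(rate - expected) <= 3 * np.sqrt(expected * (1 - expected) / sim.n_sim)

    def test_degenerate_raises(self):
        from randeval.nct import DegenerateDesignError

        with pytest.raises(DegenerateDesignError):
            simulate_rejection_rate([1, 1, 1], np.zeros(3), SimulationConfig(n_sim=10, seed=0))
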