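"""Linearized characteristic analysis: sinc minimum, onset threshold,
oscillation frequencies, and growth-exponent relations."""

import math

import numpy as np
import pytest

from delayepi import (
    EpidemicParams,
    InvalidParameterError,
    OutOfRegimeError,
    characteristic_residual,
    critical_tau_I,
    cumulative_excess_series,
    estimate_initial_growth,
    gamma0,
    growth_exponent_beta,
    growth_fit_window,
    infectious_series,
    integrate_nrde,
    oscillation_count,
    oscillation_frequencies,
    refine_mode,
    sinc,
    sinc_min_location,
    tau_I_from_beta,
)


def brute_force_sinc_minimum():
    """Oracle: dense grid scan of sin(x)/x over (0, 10)."""
    x = np.arange(1e-5, 10.0, 1e-5)
    y = np.sin(x) / x
    k = int(np.argmin(y))
    return x[k], y[k]


class TestSincMinimum:
    def test_removable_singularity(self):
        assert sinc(0.0) == 1.0

    def test_matches_grid_scan_oracle(self):
        x_star, y_min = brute_force_sinc_minimum()
        assert sinc_min_location() == pytest.approx(x_star, abs=1e-4)
        assert gamma0() == pytest.approx(abs(y_min), abs=1e-8)

    def test_minimizer_in_first_negative_lobe(self):
        assert math.pi < sinc_min_location() < 1.5 * math.pi

    def test_printed_constant(self):
        assert round(gamma0(), 4) == 0.2172


class TestCriticalDelay:
    def test_printed_threshold_at_r0_two(self):
        assert round(critical_tau_I(2.0), 3) == 1.151

    def test_inverse_scaling_in_r0(self):
        assert critical_tau_I(4.0) == pytest.approx(critical_tau_I(2.0) / 2.0, rel=1e-14)

    def test_formula_against_independent_gamma0(self):
        _, y_min = brute_force_sinc_minimum()
        assert critical_tau_I(2.5) == pytest.approx(1.0 / (2.0 * abs(y_min) * 2.5), abs=1e-6)

    def test_nonpositive_r0_rejected(self):
        with pytest.raises(InvalidParameterError):
            critical_tau_I(0.0)


class TestOscillationFrequencies:
    def test_no_second_delay_no_oscillations(self):
        assert oscillation_frequencies(2.0, 0.0) == []

    def test_below_threshold_empty(self):
        assert oscillation_frequencies(2.0, 1.0) == []
        assert oscillation_frequencies(2.0, 1.10) == []

    def test_above_threshold_nonempty(self):
        assert len(oscillation_frequencies(2.0, 1.20)) > 0

    def test_roots_match_sign_change_scan(self):
        # oracle: brute-force scan of sin(x)/x + 1/(2 R0 tau_i) at dx = 1e-6
        r0, tau_i = 2.0, 1.4
        gamma_coef = 1.0 / (2.0 * r0 * tau_i)
        x = np.arange(1e-6, 2.0 * math.pi, 1e-6)
        f = np.sin(x) / x + gamma_coef
        crossings = x[:-1][np.diff(np.sign(f)) != 0]
        omegas = oscillation_frequencies(r0, tau_i, omega_max=2.0 * math.pi / tau_i)
        assert len(omegas) == len(crossings) == 2
        for om, xc in zip(omegas, crossings):
            assert om * tau_i == pytest.approx(xc, abs=1e-5)
        # first negative sinc lobe
        assert all(math.pi < om * tau_i < 2.0 * math.pi for om in omegas)

    @pytest.mark.parametrize("r0,tau_i", [(2.0, 1.2), (2.0, 1.4), (3.0, 1.0), (2.5, 2.0)])
    def test_every_root_satisfies_the_sinc_condition(self, r0, tau_i):
        gamma_coef = 1.0 / (2.0 * r0 * tau_i)
        for om in oscillation_frequencies(r0, tau_i):
            assert abs(sinc(om * tau_i) + gamma_coef) < 1e-9
            assert om > 0


class TestGrowthExponent:
    def test_vanishes_at_the_epidemic_threshold(self):
        assert growth_exponent_beta(1.0001, 1.0) < 1e-3

    def test_subcritical_is_out_of_regime(self):
        with pytest.raises(OutOfRegimeError):
            growth_exponent_beta(0.9, 1.0)

    def test_zero_latency_residual(self):
        beta = growth_exponent_beta(2.0, 0.0)
        assert abs(beta / (1.0 - math.exp(-beta)) - 2.0) < 1e-10

    @pytest.mark.parametrize("r0,tau_i", [(1.5, 0.5), (2.5, 0.0), (2.5, 1.0), (2.5, 1.5)])
    def test_residual_at_root(self, r0, tau_i):
        beta = growth_exponent_beta(r0, tau_i)
        assert abs(r0 - beta * math.exp(beta * tau_i) / (1.0 - math.exp(-beta))) < 1e-9

    def test_latency_moderates_growth(self):
        betas = [growth_exponent_beta(2.5, ti) for ti in (0.0, 1.0, 1.5)]
        assert betas[0] > betas[1] > betas[2]


class TestInverseRelation:
    def test_round_trip(self):
        beta = growth_exponent_beta(2.5, 1.0)
        assert tau_I_from_beta(beta, 2.5) == pytest.approx(1.0, abs=1e-8)

    def test_constraint_violation_rejected(self):
        # beta/(1 - e^-beta) >= R0 would require tau_i <= 0
        with pytest.raises(OutOfRegimeError):
            tau_I_from_beta(5.0, 2.0)

    def test_forward_inverse_consistency_on_a_sweep(self):
        r0 = 2.0
        betas = np.linspace(0.05, 0.6, 8)
        tau_is = [tau_I_from_beta(b, r0) for b in betas]
        assert all(a > b for a, b in zip(tau_is, tau_is[1:]))  # beta falls as tau_i rises
        for b, ti in zip(betas, tau_is):
            assert growth_exponent_beta(r0, ti) == pytest.approx(b, abs=1e-8)


class TestCharacteristicResidual:
    def test_real_mode_consistency(self):
        beta = growth_exponent_beta(2.5, 1.0)
        assert characteristic_residual(beta, 0.0, 2.5, 1.0) < 1e-10

    def test_alpha_zero_root_is_approximate(self):
        # the sinc condition comes from squaring the real/imaginary parts,
        # so its roots satisfy the full complex relation only approximately
        r0, tau_i = 2.0, 1.4
        om = oscillation_frequencies(r0, tau_i)[0]
        res = characteristic_residual(0.0, om, r0, tau_i)
        assert res > 0.0

    def test_refined_mode_lies_between_the_sinc_roots(self):
        r0, tau_i = 2.0, 1.4
        om_lo, om_hi = oscillation_frequencies(r0, tau_i)[:2]
        _, omega, res = refine_mode(r0, tau_i, om_lo)
        assert res < 1e-8
        assert om_lo < omega < om_hi

    def test_refinement_beats_dense_grid_scan(self):
        r0, tau_i = 2.0, 1.4
        om = oscillation_frequencies(r0, tau_i)[0]
        alpha, omega, res = refine_mode(r0, tau_i, om)
        assert res < 1e-8
        assert abs(alpha) < 0.5
        # oracle: best point of a dense residual grid around the seed
        a_grid = np.linspace(-0.5, 0.5, 201)
        w_grid = np.linspace(om - 1.0, om + 1.0, 201)
        best = min(
            characteristic_residual(a, w, r0, tau_i) for a in a_grid for w in w_grid
        )
        assert res <= best + 1e-10


class TestSimulationConsistency:
    @pytest.mark.parametrize("tau_i,expect_oscillatory", [
        (0.80, False), (1.00, False), (1.20, True), (1.40, True),
    ])
    def test_onset_threshold_matches_simulation(self, tau_i, expect_oscillatory):
        p = EpidemicParams(r0=2.0, tau_i=tau_i, s0=0.99)
        traj = integrate_nrde(p, horizon=40.0, step=0.01)
        count = oscillation_count(infectious_series(traj), tau_i)
        omegas = oscillation_frequencies(2.0, tau_i)
        if expect_oscillatory:
            assert count >= 2
            assert len(omegas) > 0
        else:
            assert count <= 1
            assert omegas == []

    def test_simulated_undulation_period_matches_refined_mode(self):
        # spacing of successive pre-peak maxima of i(tau) ~ 2 pi / omega
        r0, tau_i = 2.0, 1.4
        p = EpidemicParams(r0=r0, tau_i=tau_i, s0=0.99)
        traj = integrate_nrde(p, horizon=40.0, step=0.01)
        i = infectious_series(traj)
        vals = i.to_numpy()
        tau = i.index.to_numpy()
        pk = int(np.argmax(vals))
        from scipy.signal import find_peaks
        idx, _ = find_peaks(vals[:pk], prominence=0.01 * vals[pk])
        spacings = np.diff(tau[idx])
        _, omega, _ = refine_mode(r0, tau_i, oscillation_frequencies(r0, tau_i)[0])
        assert np.mean(spacings) == pytest.approx(2.0 * math.pi / omega, rel=0.1)

    @pytest.mark.parametrize("r0,tau_i", [(1.5, 0.5), (1.5, 1.0), (2.5, 0.5), (2.5, 1.0)])
    def test_early_growth_matches_characteristic_root(self, r0, tau_i):
        beta = growth_exponent_beta(r0, tau_i)
        p = EpidemicParams(r0=r0, tau_i=tau_i, s0=0.9999)
        traj = integrate_nrde(p, horizon=30.0, step=0.01)
        me = cumulative_excess_series(traj)
        window = growth_fit_window(me, p.m0)
        slope = estimate_initial_growth(me, window)
        assert slope == pytest.approx(beta, rel=0.05)
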