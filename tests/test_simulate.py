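"""Mechanistic assay simulator: limits, conservation, protocols."""
import math

import numpy as np
import pytest

from slowbind import (
    ConfigError,
    DEFAULT_ASSAYS,
    MechanismTruth,
    closed_form_kobs,
    closed_form_rates,
    default_noise_sd,
    fit_progress_curve,
    integrated_rate_equation,
    simulate_jump_dilution,
    simulate_preincubation_assay,
    simulate_progress_curve,
)
from slowbind.simulate import conversion, enzyme_total, inhibitor_total

ASSAY = DEFAULT_ASSAYS["beta_tryptase"]
NONE = MechanismTruth(kind="none")
E0 = 1e-3


def initial_slope(curve):
    return (curve.signal[1] - curve.signal[0]) / (curve.times[1] - curve.times[0])


class TestProgressCurveSimulation:
    def test_uninhibited_michaelis_menten_initial_slope(self):
        curve = simulate_progress_curve(NONE, ASSAY, 0.0, E0)
        expected = ASSAY.signal_coeff * ASSAY.kcat * E0 * ASSAY.S0 / (ASSAY.Km + ASSAY.S0)
        assert initial_slope(curve) == pytest.approx(expected, rel=1e-3)
        assert np.all(np.diff(curve.signal) >= 0)

    def test_default_kcat_keeps_conversion_near_five_percent(self):
        curve = simulate_progress_curve(NONE, ASSAY, 0.0, E0)
        assert 0.03 < conversion(curve) < 0.07

    def test_detection_is_linear_in_signal_coefficient(self):
        import dataclasses

        truth = MechanismTruth(kind="two_step_reversible", k3=0.01, k4=0.1, k5=0.01, k6=0.001)
        a1 = simulate_progress_curve(truth, ASSAY, 10.0, E0, a0_offset=0.05, seed=5)
        doubled = dataclasses.replace(ASSAY, signal_coeff=2 * ASSAY.signal_coeff)
        a2 = simulate_progress_curve(truth, doubled, 10.0, E0, a0_offset=0.05, seed=5)
        np.testing.assert_allclose(a2.signal - 0.05, 2 * (a1.signal - 0.05), rtol=1e-9)

    def test_seeded_reproducibility_is_bitwise(self):
        kw = dict(noise_sd=0.1, seed=77)
        a = simulate_progress_curve(NONE, ASSAY, 0.0, E0, **kw)
        b = simulate_progress_curve(NONE, ASSAY, 0.0, E0, **kw)
        assert np.array_equal(a.signal, b.signal)

    def test_mass_conservation_of_enzyme_and_inhibitor(self):
        truth = MechanismTruth(kind="two_step_reversible", k3=1.0, k4=7.9, k5=0.01, k6=1e-3)
        curve = simulate_progress_curve(truth, ASSAY, 10.0, E0)
        et, it = enzyme_total(curve), inhibitor_total(curve)
        assert np.max(np.abs(et - E0)) / E0 < 1e-8
        assert np.max(np.abs(it - 10.0)) / 10.0 < 1e-8

    def test_fitted_kobs_matches_exact_relaxation_eigenvalue(self):
        # Slow first binding step (k3[I]+k4 only ~20x the isomerization):
        # the trace relaxes at the exact slow eigenvalue of the linearized
        # E<->EI<->E*I chain, a few percent below the rapid-equilibrium
        # hyperbola. The fit recovers the eigenvalue; the closed form is
        # good to its stated validity (~5% here).
        truth = MechanismTruth(kind="two_step_reversible", k3=0.01, k4=0.1, k5=0.01, k6=0.001)
        inhibitor = 10.0
        curve = simulate_progress_curve(truth, ASSAY, inhibitor, E0)
        fit = fit_progress_curve(curve)
        a = truth.k3 * inhibitor / ASSAY.competition_factor
        s = a + truth.k4 + truth.k5 + truth.k6
        p = a * (truth.k5 + truth.k6) + truth.k4 * truth.k6
        exact = (s - math.sqrt(s * s - 4 * p)) / 2.0
        assert fit.kobs == pytest.approx(exact, rel=0.01)
        assert closed_form_kobs(truth, ASSAY, inhibitor) == pytest.approx(exact, rel=0.06)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ConfigError):
            simulate_progress_curve(NONE, ASSAY, -1.0, E0)
        with pytest.raises(ConfigError):
            simulate_progress_curve(NONE, ASSAY, 0.0, E0, n_points=5)
        with pytest.raises(ConfigError):
            simulate_progress_curve(NONE, ASSAY, 0.0, E0, duration=-10.0)


class TestPreincubation:
    def test_zero_preincubation_matches_substrate_start_protocol(self):
        truth = MechanismTruth(kind="two_step_irreversible", k3=1.0, k4=10.0, k5=0.01)
        pre = simulate_preincubation_assay(truth, ASSAY, 2.0, E0, t_pre=0.0)
        direct = simulate_progress_curve(truth, ASSAY, 2.0, E0)
        assert initial_slope(pre) == pytest.approx(initial_slope(direct), rel=1e-6)

    def test_one_step_survival_is_exponential_in_dose_and_time(self):
        k3 = 0.002
        truth = MechanismTruth(kind="one_step_irreversible", k3=k3)
        control = simulate_preincubation_assay(truth, ASSAY, 0.0, 1e-4, t_pre=900.0)
        v0 = fit_progress_curve(control).v_i
        for inhibitor in (0.5, 1.0, 3.0):
            treated = simulate_preincubation_assay(truth, ASSAY, inhibitor, 1e-4, t_pre=900.0)
            ratio = fit_progress_curve(treated).v_i / v0
            assert ratio == pytest.approx(math.exp(-k3 * inhibitor * 900.0), rel=0.01)

    def test_uninhibited_truth_retains_full_activity(self):
        pre = simulate_preincubation_assay(NONE, ASSAY, 5.0, E0, t_pre=900.0)
        direct = simulate_progress_curve(NONE, ASSAY, 0.0, E0)
        assert initial_slope(pre) == pytest.approx(initial_slope(direct), rel=1e-3)


class TestJumpDilution:
    def test_uninhibited_truth_treated_equals_control(self):
        control, treated = simulate_jump_dilution(NONE, ASSAY, 1.0, E0, fold_dilution=10)
        assert initial_slope(treated) == pytest.approx(initial_slope(control), rel=1e-6)

    def test_irreversible_complex_never_regenerates_activity(self):
        truth = MechanismTruth(kind="two_step_irreversible", k3=1.0, k4=10.0, k5=0.15)
        control, treated = simulate_jump_dilution(truth, ASSAY, 0.04, E0, fold_dilution=100)
        slopes_t = np.diff(treated.signal) / np.diff(treated.times)
        slopes_c = np.diff(control.signal) / np.diff(control.times)
        assert np.all(slopes_t < 0.01 * np.max(slopes_c))

    def test_reversible_complex_recovers_at_dissociation_rate(self):
        truth = MechanismTruth(kind="two_step_reversible", k3=1.0, k4=10.0, k5=0.01, k6=0.001)
        ic50 = truth.KIstar_intrinsic * ASSAY.competition_factor
        control, treated = simulate_jump_dilution(truth, ASSAY, ic50, E0, fold_dilution=100)
        t, p = treated.times, treated.states[5]
        rate_start = (p[1] - p[0]) / (t[1] - t[0])
        rate_1800 = (p[-1] - p[-2]) / (t[-1] - t[-2])
        assert rate_1800 >= 2.0 * rate_start  # recovery half-time ~ ln2/k6 ~ 693 s
        assert np.all(np.diff(p, 2) > -1e-12)  # positive curvature throughout

    def test_dilution_factor_restricted_to_protocol_values(self):
        with pytest.raises(ConfigError):
            simulate_jump_dilution(NONE, ASSAY, 1.0, E0, fold_dilution=50)


class TestReducedModelOracle:
    def test_noiseless_traces_reproduced_by_integrated_rate_equation(self, oracle_draws):
        # full mass-action traces vs A(t) = A0 + v_s t + (v_i-v_s)(1-e^-kt)/k
        # with closed-form v_i, v_s, kobs, in the pseudo-first-order regime
        for truth, inhibitor, enzyme in oracle_draws[:10]:
            curve = simulate_progress_curve(truth, ASSAY, inhibitor, enzyme)
            assert conversion(curve) <= 0.10
            v_i, v_s = closed_form_rates(truth, ASSAY, inhibitor, enzyme)
            model = integrated_rate_equation(
                curve.times, curve.signal[0],
                v_i * ASSAY.signal_coeff, v_s * ASSAY.signal_coeff,
                closed_form_kobs(truth, ASSAY, inhibitor),
            )
            mismatch = np.max(np.abs(model - curve.signal)) / np.ptp(curve.signal)
            assert mismatch < 0.01
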