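"""Secondary inference: k_app, equilibrium constants, mechanism calls."""
import math

import numpy as np
import pytest

from slowbind import (
    ConfigError,
    DEFAULT_ASSAYS,
    FitError,
    MechanismTruth,
    classify_mechanism,
    closed_form_kobs,
    correct_for_substrate,
    estimate_equilibrium_constants,
    estimate_kapp,
    fit_progress_curve,
    ic50_from_inactivation,
)
from slowbind.doseresponse import JumpDilutionResult
from slowbind.kinetics import single_point_K
from slowbind.progress import CurveFit

ASSAY = DEFAULT_ASSAYS["beta_tryptase"]


def stub_fit(inhibitor, kobs=math.nan, v_i=1.0, v_s=0.0, identifiable=True):
    return CurveFit(
        curve_id=f"I={inhibitor}", A0=0.0, v_i=v_i, v_s=v_s, kobs=kobs,
        se_vi=0.0, se_vs=0.0, se_kobs=0.0, rss=0.0, converged=True,
        identifiable=identifiable, pfo_ok=True, conversion_ok=True,
        inhibitor_conc=inhibitor, enzyme_conc=1e-3, n_points=181,
    )


class TestEstimateKapp:
    def test_pure_linear_kobs_gives_exact_slope(self):
        fits = [stub_fit(i, kobs=0.002 * i) for i in (1, 2, 5, 10, 20)]
        est = estimate_kapp(fits)
        assert est.k_app == pytest.approx(2000.0, rel=1e-9)
        assert not est.saturating
        assert est.linear_region == (1, 2, 5, 10, 20)

    def test_saturating_kobs_reports_tangent_at_origin(self):
        k5, K1p = 0.01, 20.0
        fits = [stub_fit(i, kobs=k5 * i / (i + K1p)) for i in (0.5, 1, 2, 4)]
        est = estimate_kapp(fits)
        assert est.saturating
        assert est.k_app == pytest.approx(k5 / K1p * 1e6, rel=0.05)  # 500 M^-1 s^-1
        assert all(c <= est.K1_prime / 3 for c in est.linear_region)

    def test_too_few_identifiable_points_not_determinable(self):
        fits = [stub_fit(1.0, kobs=0.002), stub_fit(2.0, kobs=0.004),
                stub_fit(5.0, identifiable=False)]
        est = estimate_kapp(fits)
        assert math.isnan(est.k_app)
        assert "not determinable" in est.note


class TestSubstrateCorrection:
    def test_at_km_substrate_doubles_apparent_constant(self):
        assert correct_for_substrate(1000.0, ASSAY) == pytest.approx(2000.0)

    def test_vanishing_substrate_leaves_kapp_unchanged(self):
        import dataclasses

        dilute = dataclasses.replace(ASSAY, S0=ASSAY.Km * 1e-9)
        assert correct_for_substrate(1000.0, dilute) == pytest.approx(1000.0, rel=1e-8)

    def test_trypsin3_assay_example(self):
        assert correct_for_substrate(1000.0, DEFAULT_ASSAYS["trypsin3"]) == pytest.approx(2000.0)

    def test_negative_kapp_rejected(self):
        with pytest.raises(ConfigError):
            correct_for_substrate(-5.0, ASSAY)


class TestEquilibriumConstants:
    def test_single_point_inversion(self):
        assert single_point_K(4.0, 0.5) == pytest.approx(4.0)

    def test_exact_hyperbolae_recovered_globally(self):
        K1, KIstar, v0 = 2.0, 0.2, 1.0
        fits = [
            stub_fit(i, v_i=v0 / (1 + i / K1), v_s=v0 / (1 + i / KIstar))
            for i in (0.5, 1, 2, 5, 10)
        ]
        est = estimate_equilibrium_constants(fits, v0)
        assert est.K1 == pytest.approx(K1, rel=1e-6)
        assert est.KIstar == pytest.approx(KIstar, rel=1e-6)

    def test_pointwise_method_agrees_on_exact_data(self):
        K1, KIstar, v0 = 2.0, 0.2, 1.0
        fits = [
            stub_fit(i, v_i=v0 / (1 + i / K1), v_s=v0 / (1 + i / KIstar))
            for i in (0.5, 1, 2, 5, 10)
        ]
        est = estimate_equilibrium_constants(fits, v0, method="pointwise")
        assert est.K1 == pytest.approx(K1, rel=1e-9)
        assert est.KIstar == pytest.approx(KIstar, rel=1e-9)

    def test_zero_steady_state_velocities_leave_kistar_undefined(self):
        fits = [stub_fit(i, v_i=1 / (1 + i / 2.0), v_s=0.0) for i in (1, 2, 5)]
        est = estimate_equilibrium_constants(fits, 1.0)
        assert math.isnan(est.KIstar)
        assert "irreversible" in est.note

    def test_uninhibited_initial_rates_leave_k1_undefined(self):
        fits = [stub_fit(i, v_i=1.0, v_s=0.5) for i in (1, 2, 5)]
        est = estimate_equilibrium_constants(fits, 1.0)
        assert math.isnan(est.K1)

    def test_fewer_than_three_concentrations_rejected(self):
        with pytest.raises(FitError):
            estimate_equilibrium_constants([stub_fit(1.0), stub_fit(2.0)], 1.0)


class TestClassifyMechanism:
    def test_zero_steady_state_everywhere_is_irreversible(self):
        fits = [stub_fit(i, v_s=0.0) for i in (0.5, 2, 5)]
        assert classify_mechanism(fits, 1.0) == "irreversible"

    def test_declining_nonzero_steady_state_is_reversible(self):
        ratios = {0.5: 0.8, 2: 0.5, 5: 0.29}
        fits = [stub_fit(i, v_s=r) for i, r in ratios.items()]
        assert classify_mechanism(fits, 1.0) == "reversible_slow_binding"

    def test_jump_dilution_overrides_on_conflict(self):
        fits = [stub_fit(i, v_s=0.0) for i in (0.5, 2, 5)]
        jump = JumpDilutionResult(
            fold_dilution=100, recovery="partial", recovery_rate=1e-3,
            control_rate=1.0, treated_final_rate=0.5,
        )
        assert classify_mechanism(fits, 1.0, jump=jump) == "reversible_slow_binding"

    def test_benchmark_panel_accuracy(self, classification_panel):
        correct = 0
        for series in classification_panel:
            fits = [fit_progress_curve(c) for c in series["curves"]]
            v0 = fit_progress_curve(series["control"]).v_i
            correct += classify_mechanism(fits, v0) == series["label"]
        assert correct >= 0.95 * len(classification_panel)


class TestIc50FromInactivation:
    def test_closed_form_arithmetic(self):
        assert ic50_from_inactivation(770.0, 900.0) == pytest.approx(1.0, rel=0.01)

    def test_inverse_proportionality_in_rate(self):
        assert ic50_from_inactivation(1540.0, 900.0) == pytest.approx(
            ic50_from_inactivation(770.0, 900.0) / 2
        )

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ConfigError):
            ic50_from_inactivation(0.0, 900.0)


class TestSubstrateProtection:
    def test_halving_substrate_raises_kobs_but_not_k_true(self):
        import dataclasses

        truth = MechanismTruth(kind="two_step_irreversible", k3=1.0, k4=10.0, k5=0.15)
        concs = np.geomspace(0.25, 1.2, 7)
        estimates = {}
        for s_frac in (1.0, 0.5):
            assay = dataclasses.replace(ASSAY, S0=ASSAY.Km * s_frac)
            kobs = [closed_form_kobs(truth, assay, i) for i in concs]
            assert all(
                k_half > k_full
                for k_half, k_full in zip(
                    kobs, [closed_form_kobs(truth, ASSAY, i) for i in concs]
                )
            ) or s_frac == 1.0
            est = estimate_kapp([stub_fit(i, kobs=k) for i, k in zip(concs, kobs)])
            estimates[s_frac] = correct_for_substrate(est.k_app, assay)
        assert estimates[0.5] == pytest.approx(estimates[1.0], rel=0.05)
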