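"""Triage, four-parameter logistic IC50, replicates, jump-dilution calls."""
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from slowbind import (
    ConfigError,
    DEFAULT_ASSAYS,
    MechanismTruth,
    aggregate_replicates,
    analyze_jump_dilution,
    fit_ic50,
    screen_triage,
    simulate_jump_dilution,
)
from slowbind.protocols import run_preincubation_ic50

ASSAY = DEFAULT_ASSAYS["beta_tryptase"]


class TestScreenTriage:
    @pytest.mark.parametrize(
        "activity_at_10, expected",
        [(0.40, "proceed"), (0.50, "proceed"), (0.60, "above_10uM")],
    )
    def test_fifty_percent_cut_is_boundary_inclusive(self, activity_at_10, expected):
        assert screen_triage({10.0: activity_at_10, 1.0: 0.9, 0.1: 1.0}) == expected

    def test_missing_screen_concentration_rejected(self):
        with pytest.raises(ConfigError):
            screen_triage({10.0: 0.4, 1.0: 0.9})


class TestFitIc50:
    def test_exact_logistic_data_self_consistency(self):
        concs = np.geomspace(0.005, 50.0, 8)
        acts = 1.0 / (1.0 + concs / 0.5)  # top=1, bottom=0, hill=1
        res = fit_ic50(concs, acts)
        assert res.ic50 == pytest.approx(0.5, rel=1e-6)
        assert res.hill == pytest.approx(1.0, rel=1e-6)
        assert res.top == pytest.approx(1.0, abs=1e-6)
        assert res.bottom == pytest.approx(0.0, abs=1e-6)

    def test_flat_full_activity_flags_no_inhibition(self):
        concs = np.geomspace(0.01, 10.0, 6)
        res = fit_ic50(concs, np.ones_like(concs))
        assert math.isinf(res.ic50)
        assert not res.converged and not res.in_range
        assert res.ic50 > concs.max()

    def test_narrow_design_rejected(self):
        with pytest.raises(Exception):
            fit_ic50([1, 2, 3, 4, 5], [1, 0.8, 0.6, 0.4, 0.2])

    def test_no_inhibition_truth_never_yields_finite_ic50(self):
        truth = MechanismTruth(kind="none")
        concs = np.geomspace(0.001, 1.0, 6)
        for seed in range(20):
            res, _ = run_preincubation_ic50(
                truth, ASSAY, concs, enzyme_conc=2e-5, seed=seed
            )
            assert not math.isfinite(res.ic50) or res.ic50 > concs.max()


class TestAggregateReplicates:
    def test_identical_replicates(self):
        mean, sd, needs_third = aggregate_replicates([0.1, 0.1])
        assert (mean, sd, needs_third) == (pytest.approx(0.1), pytest.approx(0.0), False)

    def test_widely_split_replicates_under_printed_rule(self):
        mean, sd, needs_third = aggregate_replicates([0.1, 0.9])
        assert mean == pytest.approx(0.5)
        assert sd == pytest.approx(0.5657, rel=1e-3)
        assert needs_third is False  # 0.566 < 3 * 0.5 as printed

    def test_alternative_threshold_reading_can_fire(self):
        _, _, needs_third = aggregate_replicates([0.1, 0.9], threshold_ratio=1 / 3)
        assert needs_third is True  # 0.566 > 0.5/3

    def test_single_replicate_has_no_spread(self):
        mean, sd, needs_third = aggregate_replicates([0.2])
        assert mean == pytest.approx(0.2)
        assert math.isnan(sd) and needs_third is None

    @given(st.floats(1e-6, 1e3), st.floats(1e-6, 1e3))
    def test_printed_rule_unreachable_for_two_positive_replicates(self, a, b):
        # SD = |a-b|/sqrt(2) <= sqrt(2)*mean < 3*mean: the printed trigger
        # can never fire at n=2; documented here as the rule's anomaly.
        _, _, needs_third = aggregate_replicates([a, b])
        assert needs_third is False


class TestAnalyzeJumpDilution:
    def test_treated_identical_to_control_is_full_recovery(self):
        control, _ = simulate_jump_dilution(
            MechanismTruth(kind="none"), ASSAY, 1.0, 1e-3, fold_dilution=10
        )
        result = analyze_jump_dilution(control, control)
        assert result.recovery == "full"

    def test_completely_inactivated_enzyme_shows_no_recovery(self):
        truth = MechanismTruth(kind="two_step_irreversible", k3=1.0, k4=10.0, k5=0.15)
        control, treated = simulate_jump_dilution(truth, ASSAY, 0.04, 1e-3, fold_dilution=100)
        result = analyze_jump_dilution(control, treated)
        assert result.recovery == "none"
        assert result.recovery_rate is None

    def test_slow_dissociation_recovers_at_expected_rate(self):
        k6 = 0.001
        truth = MechanismTruth(kind="two_step_reversible", k3=1.0, k4=10.0, k5=0.01, k6=k6)
        ic50 = truth.KIstar_intrinsic * ASSAY.competition_factor
        control, treated = simulate_jump_dilution(truth, ASSAY, ic50, 1e-3, fold_dilution=100)
        result = analyze_jump_dilution(control, treated)
        assert result.recovery in ("partial", "full")
        residual = ic50 * 10 / 100
        expected = k6 + truth.k5 * residual / (
            residual + truth.K1_intrinsic * ASSAY.competition_factor
        )
        assert result.recovery_rate == pytest.approx(expected, rel=0.30)

    def test_mismatched_time_grids_rejected(self):
        control, treated = simulate_jump_dilution(
            MechanismTruth(kind="none"), ASSAY, 1.0, 1e-3, fold_dilution=10
        )
        import dataclasses

        shifted = dataclasses.replace(
            treated, times=treated.times[:-1], signal=treated.signal[:-1]
        )
        with pytest.raises(ConfigError):
            analyze_jump_dilution(control, shifted)

    def test_jump_dilution_agrees_with_progress_curve_classification(
        self, classification_panel
    ):
        from slowbind import classify_mechanism, fit_progress_curve

        agree = 0
        for series in classification_panel:
            fits = [fit_progress_curve(c) for c in series["curves"]]
            v0 = fit_progress_curve(series["control"]).v_i
            call = classify_mechanism(fits, v0)
            jd = analyze_jump_dilution(*series["jump"])
            jd_call = "irreversible" if jd.recovery == "none" else "reversible_slow_binding"
            agree += jd_call == call
        assert agree >= 0.95 * len(classification_panel)
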