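"""End-to-end simulated experiments: simulate -> fit -> infer.

These helpers wire the simulator to the analysis stages the way a bench
campaign would be run: a kinetic dilution series with its uninhibited
control, and a preincubation dose-response. They are used by the test
suite, the reproduction script and the CLI alike.
"""
from __future__ import annotations

import math

import numpy as np

from .assays import EnzymeAssay, default_noise_sd
from .doseresponse import Logistic4PL, fit_ic50
from .kinetics import RateProfile, build_rate_profile
from .mechanism import MechanismTruth
from .progress import CurveFit, fit_progress_curve
from .simulate import (
    ProgressCurve,
    simulate_preincubation_assay,
    simulate_progress_curve,
)


def run_inhibition_series(
    truth: MechanismTruth,
    assay: EnzymeAssay,
    concentrations,
    enzyme_conc: float = 1e-3,
    noise_fraction: float = 0.01,
    seed: int | None = None,
    duration: float = 1800.0,
    n_points: int = 181,
    compound_id: str = "probe",
    jump=None,
) -> tuple[RateProfile, list[CurveFit]]:
    """Simulate and analyze one kinetic dilution series (control + [I] grid)."""
    rng = np.random.default_rng(seed)
    noise_sd = default_noise_sd(assay, enzyme_conc, duration, noise_fraction)
    fits = []
    for conc in [0.0, *concentrations]:
        curve = simulate_progress_curve(
            truth, assay, conc, enzyme_conc,
            duration=duration, n_points=n_points, noise_sd=noise_sd,
            seed=int(rng.integers(2**31)),
        )
        fits.append(fit_progress_curve(curve))
    profile = build_rate_profile(compound_id, assay.enzyme_id, fits, assay, jump=jump)
    return profile, fits


def run_preincubation_ic50(
    truth: MechanismTruth,
    assay: EnzymeAssay,
    concentrations,
    enzyme_conc: float = 1e-4,
    t_pre: float = 900.0,
    noise_fraction: float = 0.02,
    seed: int | None = None,
    measure_window: float = 1800.0,
    n_points: int = 181,
) -> tuple[Logistic4PL, np.ndarray]:
    """Simulated preincubation dose-response and its 4PL fit.

    Residual activity at each concentration is the fitted initial rate of
    the post-addition trace relative to the preincubated uninhibited
    control — the quantity the 4PL expects for slow-binding compounds,
    whose rate drifts during the measurement itself.
    """
    rng = np.random.default_rng(seed)
    noise_sd = default_noise_sd(assay, enzyme_conc, measure_window, noise_fraction)

    def residual_vi(conc: float) -> float:
        curve = simulate_preincubation_assay(
            truth, assay, conc, enzyme_conc, t_pre=t_pre,
            measure_window=measure_window, n_points=n_points,
            noise_sd=noise_sd, seed=int(rng.integers(2**31)),
        )
        return fit_progress_curve(curve).v_i

    v0 = residual_vi(0.0)
    if not v0 > 0:
        raise ValueError("uninhibited control produced no measurable rate")
    activities = np.array([residual_vi(c) / v0 for c in concentrations])
    return fit_ic50(np.asarray(concentrations, dtype=float), activities), activities
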