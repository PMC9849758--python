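"""Mechanistic simulator of continuous protease inhibition assays.

Integrates the full mass-action network

    E + S ⇌(k_on_S, k_off_S) ES →(kcat) E + P
    E + I ⇌(k3, k4) EI ⇌(k5, k6) E*I

from [P] = 0 and converts released product to detector signal
(AU) through the assay's linear signal coefficient, with optional
additive i.i.d. Gaussian detection noise. Substrate binding
microscopics are fixed at k_on_S = 10 μM⁻¹ s⁻¹ with
k_off_S = k_on_S·Km − kcat, which reproduces the assay Km exactly.

Besides plain progress curves the module implements the two bench
protocols used to characterize probes: preincubation (enzyme+inhibitor
without substrate, then substrate addition) and jump dilution
(preincubation at 10×IC50 and 2.5× enzyme, then 10- or 100-fold
dilution into substrate).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .assays import DEFAULT_DURATION, DEFAULT_N_POINTS, EnzymeAssay
from .errors import ConfigError, SimulationError
from .mechanism import MechanismKind, MechanismTruth

#: Fixed substrate association rate (μM⁻¹ s⁻¹); not identifiable from Km
#: alone, chosen fast enough that substrate binding is always at
#: quasi-steady state on the plate-reader time scale.
K_ON_S = 10.0

_RTOL = 1e-8
_ATOL = 1e-10

# state vector indices: free enzyme, ES, EI, E*I, substrate, product, free inhibitor
_E, _ES, _EI, _ESI, _S, _P, _I = range(7)


@dataclass
class ProgressCurve:
    """One time-course trace with its concentrations and assay condition."""

    curve_id: str
    times: np.ndarray          # s, strictly increasing, start >= 0
    signal: np.ndarray         # AU, same length as times
    inhibitor_conc: float      # [I]0, μM
    enzyme_conc: float         # [E]0, μM
    assay: EnzymeAssay | None = None
    truth: MechanismTruth | None = None
    seed: int | None = None
    states: np.ndarray | None = field(default=None, repr=False)  # (7, n), noiseless

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.ndim != 1 or self.times.size != self.signal.size:
            raise ConfigError(f"{self.curve_id}: times/signal must be equal-length 1-D series")
        if self.times.size and (self.times[0] < 0 or np.any(np.diff(self.times) <= 0)):
            raise ConfigError(f"{self.curve_id}: times must be strictly increasing and start >= 0")
        if self.inhibitor_conc < 0:
            raise ConfigError(f"{self.curve_id}: inhibitor_conc must be >= 0")
        if self.enzyme_conc <= 0:
            raise ConfigError(f"{self.curve_id}: enzyme_conc must be > 0")


def _substrate_params(assay: EnzymeAssay) -> tuple[float, float]:
    koff = K_ON_S * assay.Km - assay.kcat
    if koff < 0:
        raise ConfigError(
            f"{assay.enzyme_id}: kcat={assay.kcat} exceeds k_on_S*Km; "
            "no non-negative k_off_S reproduces this Km"
        )
    return K_ON_S, koff


def _rhs(t, y, kon_s, koff_s, kcat, k3, k4, k5, k6):
    e, es, ei, esi, s, p, i = y
    v_bind_s = kon_s * e * s - koff_s * es
    v_cat = kcat * es
    v_bind_i = k3 * e * i - k4 * ei
    v_isom = k5 * ei - k6 * esi
    return (
        -v_bind_s + v_cat - v_bind_i,   # E
        v_bind_s - v_cat,               # ES
        v_bind_i - v_isom,              # EI
        v_isom,                         # E*I
        -v_bind_s,                      # S
        v_cat,                          # P
        -v_bind_i,                      # I
    )


def _integrate(
    y0: np.ndarray,
    t_eval: np.ndarray,
    assay: EnzymeAssay,
    truth: MechanismTruth,
    curve_id: str,
    with_substrate: bool = True,
) -> np.ndarray:
    kon_s, koff_s = _substrate_params(assay)
    kcat = assay.kcat
    if not with_substrate:
        kon_s = koff_s = kcat = 0.0
    args = (kon_s, koff_s, kcat, truth.k3, truth.k4, truth.k5, truth.k6)
    sol = solve_ivp(
        _rhs,
        (0.0, float(t_eval[-1])),
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=_RTOL,
        atol=_ATOL,
        args=args,
    )
    if not sol.success or sol.y.shape[1] != t_eval.size:
        raise SimulationError(f"integration failed for curve {curve_id!r}: {sol.message}")
    return sol.y


def _emit(
    states: np.ndarray,
    times: np.ndarray,
    assay: EnzymeAssay,
    truth: MechanismTruth,
    inhibitor_conc: float,
    enzyme_conc: float,
    noise_sd: float,
    seed: int | None,
    a0_offset: float,
    curve_id: str,
) -> ProgressCurve:
    signal = a0_offset + assay.signal_coeff * states[_P]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=signal.size)
    return ProgressCurve(
        curve_id=curve_id,
        times=times,
        signal=signal,
        inhibitor_conc=inhibitor_conc,
        enzyme_conc=enzyme_conc,
        assay=assay,
        truth=truth,
        seed=seed,
        states=states,
    )


def _check_sim_args(duration, n_points, noise_sd, inhibitor_conc, enzyme_conc):
    if duration <= 0:
        raise ConfigError("duration must be > 0")
    if n_points < 10:
        raise ConfigError("n_points must be >= 10")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    if inhibitor_conc < 0:
        raise ConfigError("inhibitor_conc must be >= 0")
    if enzyme_conc <= 0:
        raise ConfigError("enzyme_conc must be > 0")


def simulate_progress_curve(
    truth: MechanismTruth,
    assay: EnzymeAssay,
    inhibitor_conc: float,
    enzyme_conc: float,
    duration: float = DEFAULT_DURATION,
    n_points: int = DEFAULT_N_POINTS,
    noise_sd: float = 0.0,
    seed: int | None = None,
    a0_offset: float = 0.0,
    curve_id: str | None = None,
) -> ProgressCurve:
    """Simulate a substrate-start progress curve (inhibitor + substrate
    present from t=0, reaction started by adding enzyme)."""
    _check_sim_args(duration, n_points, noise_sd, inhibitor_conc, enzyme_conc)
    times = np.linspace(0.0, duration, n_points)
    curve_id = curve_id or f"{assay.enzyme_id}:I={inhibitor_conc:g}"
    y0 = np.zeros(7)
    y0[_E] = enzyme_conc
    y0[_S] = assay.S0
    y0[_I] = inhibitor_conc
    states = _integrate(y0, times, assay, truth, curve_id)
    return _emit(states, times, assay, truth, inhibitor_conc, enzyme_conc,
                 noise_sd, seed, a0_offset, curve_id)


def simulate_preincubation_assay(
    truth: MechanismTruth,
    assay: EnzymeAssay,
    inhibitor_conc: float,
    enzyme_conc: float,
    t_pre: float = 900.0,
    measure_window: float = DEFAULT_DURATION,
    n_points: int = DEFAULT_N_POINTS,
    noise_sd: float = 0.0,
    seed: int | None = None,
    a0_offset: float = 0.0,
    curve_id: str | None = None,
) -> ProgressCurve:
    """Preincubate enzyme with inhibitor (no substrate) for ``t_pre``
    seconds, then add substrate at S0 and record the measurement phase.

    Substrate addition is modeled without volume change; the returned
    curve covers the measurement phase only, with time zero at substrate
    addition.
    """
    if t_pre < 0:
        raise ConfigError("t_pre must be >= 0")
    _check_sim_args(measure_window, n_points, noise_sd, inhibitor_conc, enzyme_conc)
    curve_id = curve_id or f"{assay.enzyme_id}:pre:I={inhibitor_conc:g}"
    y0 = np.zeros(7)
    y0[_E] = enzyme_conc
    y0[_I] = inhibitor_conc
    if t_pre > 0:
        pre = _integrate(y0, np.array([0.0, t_pre]), assay, truth, curve_id,
                         with_substrate=False)
        y0 = pre[:, -1].copy()
    y0[_S] = assay.S0
    y0[_P] = 0.0
    times = np.linspace(0.0, measure_window, n_points)
    states = _integrate(y0, times, assay, truth, curve_id)
    return _emit(states, times, assay, truth, inhibitor_conc, enzyme_conc,
                 noise_sd, seed, a0_offset, curve_id)


def simulate_jump_dilution(
    truth: MechanismTruth,
    assay: EnzymeAssay,
    ic50: float,
    enzyme_conc: float,
    fold_dilution: int = 100,
    t_pre: float = 900.0,
    measure_window: float = DEFAULT_DURATION,
    n_points: int = DEFAULT_N_POINTS,
    noise_sd: float = 0.0,
    seed: int | None = None,
    a0_offset: float = 0.0,
) -> tuple[ProgressCurve, ProgressCurve]:
    """Jump-dilution reversibility protocol.

    Enzyme at 2.5× ``enzyme_conc`` is incubated with inhibitor at
    10×``ic50`` for ``t_pre`` s, then all species are diluted
    ``fold_dilution``-fold into substrate at S0. Returns
    ``(control, treated)`` traces over the same window, where the
    control went through the identical protocol without inhibitor.
    """
    if ic50 <= 0:
        raise ConfigError("ic50 must be > 0")
    if fold_dilution not in (10, 100):
        raise ConfigError(f"fold_dilution must be 10 or 100, got {fold_dilution}")
    if t_pre < 0:
        raise ConfigError("t_pre must be >= 0")
    _check_sim_args(measure_window, n_points, noise_sd, 10.0 * ic50, enzyme_conc)
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, measure_window, n_points)
    curves = []
    for label, inhibitor in (("control", 0.0), ("treated", 10.0 * ic50)):
        curve_id = f"{assay.enzyme_id}:jump{fold_dilution}x:{label}"
        y0 = np.zeros(7)
        y0[_E] = 2.5 * enzyme_conc
        y0[_I] = inhibitor
        if t_pre > 0:
            pre = _integrate(y0, np.array([0.0, t_pre]), assay, truth, curve_id,
                             with_substrate=False)
            y0 = pre[:, -1].copy()
        y0 /= fold_dilution
        y0[_S] = assay.S0
        y0[_P] = 0.0
        states = _integrate(y0, times, assay, truth, curve_id)
        signal = a0_offset + assay.signal_coeff * states[_P]
        if noise_sd > 0:
            signal = signal + rng.normal(0.0, noise_sd, size=signal.size)
        curves.append(
            ProgressCurve(
                curve_id=curve_id,
                times=times,
                signal=signal,
                inhibitor_conc=inhibitor / fold_dilution,
                enzyme_conc=2.5 * enzyme_conc / fold_dilution,
                assay=assay,
                truth=truth,
                seed=seed,
                states=states,
            )
        )
    return curves[0], curves[1]


def enzyme_total(curve: ProgressCurve) -> np.ndarray:
    """Total enzyme across E, ES, EI, E*I at every stored state (μM)."""
    if curve.states is None:
        raise ConfigError(f"{curve.curve_id}: no stored states (imported trace?)")
    return curve.states[[_E, _ES, _EI, _ESI]].sum(axis=0)


def inhibitor_total(curve: ProgressCurve) -> np.ndarray:
    """Total inhibitor across I, EI, E*I at every stored state (μM)."""
    if curve.states is None:
        raise ConfigError(f"{curve.curve_id}: no stored states (imported trace?)")
    return curve.states[[_I, _EI, _ESI]].sum(axis=0)


def conversion(curve: ProgressCurve) -> float:
    """Final fractional substrate conversion [P](T)/S0 of a simulated trace."""
    if curve.states is None or curve.assay is None:
        raise ConfigError(f"{curve.curve_id}: conversion needs simulated states")
    return float(curve.states[_P, -1] / curve.assay.S0)


def random_oracle_draws(seed: int, n: int = 50, assay: EnzymeAssay | None = None):
    """Random mechanisms + conditions in the pseudo-first-order regime.

    Each draw satisfies the assumptions of the closed-form analysis:
    [I]0 >= 10·[E]0, rapid first-step equilibration (k3·[I]+k4 far above
    k5+k6), observed rate constants that both develop and resolve within
    the default 30-min window, and low substrate conversion. Returns a
    list of (truth, inhibitor_conc, enzyme_conc) triples — the draw set
    used to validate simulated traces against the closed forms.
    """
    from .assays import DEFAULT_ASSAYS

    assay = assay or DEFAULT_ASSAYS["beta_tryptase"]
    rng = np.random.default_rng(seed)
    kinds = (
        MechanismKind.ONE_STEP_IRREVERSIBLE,
        MechanismKind.TWO_STEP_IRREVERSIBLE,
        MechanismKind.TWO_STEP_REVERSIBLE,
    )
    draws = []
    for _ in range(n):
        kind = kinds[int(rng.integers(len(kinds)))]
        if kind is MechanismKind.ONE_STEP_IRREVERSIBLE:
            k3 = float(np.exp(rng.uniform(np.log(0.01), np.log(0.25))))
            truth = MechanismTruth(kind=kind, k3=k3)
            kobs_target = rng.uniform(2.5, 10.0) / DEFAULT_DURATION
            inhibitor = assay.competition_factor * kobs_target / k3
            enzyme = 1e-4
        else:
            K1_int = float(np.exp(rng.uniform(np.log(2.0), np.log(50.0))))
            k5 = float(np.exp(rng.uniform(np.log(4e-3), np.log(1.2e-2))))
            k6 = k5 / float(rng.uniform(3.0, 10.0)) \
                if kind is MechanismKind.TWO_STEP_REVERSIBLE else 0.0
            truth = MechanismTruth(kind=kind, k3=1.0, k4=K1_int, k5=k5, k6=k6)
            saturation = rng.uniform(0.35, 0.8)
            K1_app = K1_int * assay.competition_factor
            inhibitor = K1_app * saturation / (1.0 - saturation)
            enzyme = 1e-3
        draws.append((truth, float(inhibitor), enzyme))
    return draws


def benchmark_panel(
    seed: int,
    n_per_class: int = 10,
    concentration_factors: tuple[float, ...] = (0.5, 1.5, 4.0),
    noise_fraction: float = 0.01,
    assay: EnzymeAssay | None = None,
    enzyme_conc: float = 1e-3,
    with_jump: bool = True,
) -> list[dict]:
    """Standard mechanism-classification benchmark panel.

    Draws ``n_per_class`` two-step irreversible and ``n_per_class``
    two-step reversible mechanisms with randomized K1 (5–50 μM apparent)
    and isomerization rates, and simulates for each a three-concentration
    inhibitor series (plus uninhibited control) at default noise, plus an
    optional jump-dilution pair. Returns one dict per series with keys
    ``truth``, ``curves``, ``control``, ``jump`` and ``label``.
    """
    from .assays import DEFAULT_ASSAYS, default_noise_sd
    from .kinetics import ic50_from_inactivation

    assay = assay or DEFAULT_ASSAYS["beta_tryptase"]
    rng = np.random.default_rng(seed)
    noise_sd = default_noise_sd(assay, enzyme_conc, fraction=noise_fraction)
    series = []
    for kind in (MechanismKind.TWO_STEP_IRREVERSIBLE, MechanismKind.TWO_STEP_REVERSIBLE):
        for _ in range(n_per_class):
            K1_app = float(np.exp(rng.uniform(np.log(5.0), np.log(50.0))))
            K1_int = K1_app / assay.competition_factor
            k5 = float(rng.uniform(6.7e-3, 1.2e-2))
            k3 = 1.0
            if kind is MechanismKind.TWO_STEP_REVERSIBLE:
                k6 = k5 / float(rng.uniform(2.0, 8.0))
            else:
                k6 = 0.0
            truth = MechanismTruth(kind=kind, k3=k3, k4=k3 * K1_int, k5=k5, k6=k6)
            concs = [f * K1_app for f in concentration_factors]
            control = simulate_progress_curve(
                truth, assay, 0.0, enzyme_conc, noise_sd=noise_sd,
                seed=int(rng.integers(2**31)),
            )
            curves = [
                simulate_progress_curve(
                    truth, assay, c, enzyme_conc, noise_sd=noise_sd,
                    seed=int(rng.integers(2**31)),
                )
                for c in concs
            ]
            jump = None
            if with_jump:
                if kind is MechanismKind.TWO_STEP_REVERSIBLE:
                    ic50 = truth.KIstar_intrinsic * assay.competition_factor
                else:
                    k_true_M = 1e6 * k5 / K1_int
                    ic50 = ic50_from_inactivation(k_true_M, 900.0)
                jump_noise = default_noise_sd(
                    assay, 2.5 * enzyme_conc / 100, fraction=noise_fraction
                )
                jump = simulate_jump_dilution(
                    truth, assay, ic50, enzyme_conc, fold_dilution=100,
                    noise_sd=jump_noise, seed=int(rng.integers(2**31)),
                )
            series.append(
                {
                    "truth": truth,
                    "control": control,
                    "curves": curves,
                    "jump": jump,
                    "label": "irreversible"
                    if kind is MechanismKind.TWO_STEP_IRREVERSIBLE
                    else "reversible_slow_binding",
                }
            )
    return series
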