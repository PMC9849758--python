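"""Microscopic inhibition mechanisms and their closed-form observables.

The binding scheme, competing with substrate turnover E+S ⇌ ES → E+P, is

    E + I  ⇌(k3, k4)  EI  ⇌(k5, k6)  E*I

* ``one_step_irreversible`` — direct covalent capture: E+I →(k3) EI with
  EI terminal (k4 = k5 = k6 = 0).
* ``two_step_irreversible`` — reversible encounter complex EI followed by
  irreversible isomerization to E*I (k6 = 0).
* ``two_step_reversible`` — slow-tight binding: both steps reversible,
  overall affinity KI* = K1·k6/(k5+k6) ≤ K1.
* ``none`` — uninhibited control.

Under pseudo-first-order conditions ([I]0 ≫ [E]0) and substrate at S0,
the transition from initial to steady-state velocity within one progress
curve is exponential with observed rate constant

    kobs = k6 + k5·[I] / ([I] + K1·(1 + S0/Km))        (two-step kinds)
    kobs = k3·[I] / (1 + S0/Km)                        (one-step kind)

with K1 = k4/k3 the intrinsic first-step dissociation constant.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .assays import EnzymeAssay
from .errors import ConfigError


class MechanismKind(str, Enum):
    NONE = "none"
    ONE_STEP_IRREVERSIBLE = "one_step_irreversible"
    TWO_STEP_IRREVERSIBLE = "two_step_irreversible"
    TWO_STEP_REVERSIBLE = "two_step_reversible"


_TWO_STEP = (MechanismKind.TWO_STEP_IRREVERSIBLE, MechanismKind.TWO_STEP_REVERSIBLE)


@dataclass(frozen=True)
class MechanismTruth:
    """Ground-truth microscopic rate constants of a simulated mechanism.

    k3: association E+I → EI (μM⁻¹ s⁻¹); k4: dissociation EI → E+I (s⁻¹);
    k5: isomerization EI → E*I (s⁻¹); k6: reverse isomerization (s⁻¹).
    """

    kind: MechanismKind
    k3: float = 0.0
    k4: float = 0.0
    k5: float = 0.0
    k6: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", MechanismKind(self.kind))
        for name in ("k3", "k4", "k5", "k6"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ConfigError(f"rate constant {name} must be finite and >= 0, got {v}")
        kind = self.kind
        if kind is MechanismKind.NONE:
            if any((self.k3, self.k4, self.k5, self.k6)):
                raise ConfigError("kind 'none' must have all rate constants zero")
            return
        if self.k3 <= 0:
            raise ConfigError(f"kind {kind.value}: k3 must be > 0")
        if kind is MechanismKind.ONE_STEP_IRREVERSIBLE:
            if self.k4 != 0 or self.k5 != 0 or self.k6 != 0:
                raise ConfigError("one_step_irreversible: EI is terminal (k4=k5=k6=0)")
        elif kind is MechanismKind.TWO_STEP_IRREVERSIBLE:
            if self.k6 != 0:
                raise ConfigError("two_step_irreversible requires k6 = 0")
            if self.k5 <= 0:
                raise ConfigError("two_step_irreversible requires k5 > 0")
        elif kind is MechanismKind.TWO_STEP_REVERSIBLE:
            if self.k6 <= 0:
                raise ConfigError("two_step_reversible requires k6 > 0")
            if self.k5 <= 0:
                raise ConfigError("two_step_reversible requires k5 > 0")

    @property
    def K1_intrinsic(self) -> float:
        """Intrinsic first-step dissociation constant k4/k3 (μM)."""
        if self.kind is MechanismKind.NONE or self.k3 == 0:
            return math.nan
        return self.k4 / self.k3

    @property
    def KIstar_intrinsic(self) -> float:
        """Intrinsic overall dissociation constant K1·k6/(k5+k6) (μM)."""
        if self.kind is not MechanismKind.TWO_STEP_REVERSIBLE:
            return math.nan
        return self.K1_intrinsic * self.k6 / (self.k5 + self.k6)


def uninhibited() -> MechanismTruth:
    """Convenience constructor for the no-inhibitor control mechanism."""
    return MechanismTruth(kind=MechanismKind.NONE)


def closed_form_kobs(
    truth: MechanismTruth, assay: EnzymeAssay, inhibitor_conc: float
) -> float:
    """Pseudo-first-order observed rate constant kobs (s⁻¹).

    Closed form under rapid first-step equilibration and competitive
    substrate protection at S0; the independent reference every ODE
    trace is checked against.
    """
    if inhibitor_conc < 0:
        raise ConfigError(f"inhibitor_conc must be >= 0, got {inhibitor_conc}")
    if truth.kind is MechanismKind.NONE:
        raise ConfigError("kobs is undefined for an uninhibited mechanism")
    c = assay.competition_factor
    if truth.kind is MechanismKind.ONE_STEP_IRREVERSIBLE:
        return truth.k3 * inhibitor_conc / c
    K1_app = (truth.k4 / truth.k3) * c
    return truth.k6 + truth.k5 * inhibitor_conc / (inhibitor_conc + K1_app)


def closed_form_rates(
    truth: MechanismTruth,
    assay: EnzymeAssay,
    inhibitor_conc: float,
    enzyme_conc: float,
) -> tuple[float, float]:
    """Closed-form initial and steady-state product rates (v_i, v_s), μM/s.

    v_i reflects rapid pre-equilibration of the first binding step only
    (v_i = v0 for the one-step mechanism, which has no fast complex);
    v_s is zero for irreversible kinds and set by the overall apparent
    KI* for slow-tight binders.
    """
    v0 = assay.product_rate(enzyme_conc)
    c = assay.competition_factor
    kind = truth.kind
    if kind is MechanismKind.NONE:
        return v0, v0
    if kind is MechanismKind.ONE_STEP_IRREVERSIBLE:
        return v0, 0.0
    K1_app = (truth.k4 / truth.k3) * c
    v_i = v0 / (1.0 + inhibitor_conc / K1_app)
    if kind is MechanismKind.TWO_STEP_IRREVERSIBLE:
        return v_i, 0.0
    KIstar_app = truth.KIstar_intrinsic * c
    v_s = v0 / (1.0 + inhibitor_conc / KIstar_app)
    return v_i, v_s
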