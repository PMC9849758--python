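"""Secondary inference across an inhibitor dilution series.

Combines per-curve fits (v_i, v_s, kobs at each [I]) into:

* ``k_app`` — the apparent second-order rate constant, from the linear
  part of kobs versus [I]. Saturation is detected with an
  extra-sum-of-squares F-test of the hyperbola
  kobs = c0 + k5'·[I]/([I]+K1') against a straight line; when the
  hyperbola wins, k_app is its tangent at the origin, k5'/K1', which is
  the limit the linear part estimates.
* ``k_true = k_app·(1 + S0/Km)`` — corrected for competitive substrate
  protection.
* apparent equilibrium constants ``K1`` (from v_i/v0 = 1/(1+[I]/K1))
  and ``KI*`` (from v_s/v0 = 1/(1+[I]/KI*)), fitted globally across the
  series by default, or inverted per concentration and averaged.
* a mechanism call: irreversible (steady-state velocity ~ zero at every
  [I]) versus reversible slow binding (non-zero v_s that declines with
  [I]), optionally overridden by a jump-dilution result.

k_app and k_true are reported in M⁻¹ s⁻¹; equilibrium constants in μM.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .assays import EnzymeAssay
from .errors import ConfigError, FitError
from .progress import CurveFit

MECHANISM_IRREVERSIBLE = "irreversible"
MECHANISM_REVERSIBLE = "reversible_slow_binding"
MECHANISM_UNDETERMINED = "not_determinable"

#: v_s/v0 below this fraction counts as a zero steady-state velocity.
IRREVERSIBILITY_THRESHOLD = 0.05


@dataclass
class KappEstimate:
    k_app: float               # M⁻¹ s⁻¹ (nan when not determinable)
    se: float
    linear_region: tuple[float, ...]
    saturating: bool
    K1_prime: float            # μM; apparent half-saturation of kobs (nan if linear)
    n_points: int
    note: str = ""


@dataclass
class EquilibriumEstimate:
    K1: float                  # μM
    K1_se: float
    KIstar: float              # μM
    KIstar_se: float
    method: str
    note: str = ""


@dataclass
class RateProfile:
    """Per compound–enzyme kinetic summary (one Table-4/5-style row)."""

    compound_id: str
    enzyme_id: str
    v0: float                      # uninhibited initial rate, AU/s
    k_app: float                   # M⁻¹ s⁻¹
    k_app_se: float
    k_true: float                  # M⁻¹ s⁻¹, substrate-corrected
    K1_app: float                  # μM
    K1_se: float
    KIstar_app: float              # μM
    KIstar_se: float
    mechanism: str
    linear_region: tuple[float, ...]
    n_curves: int
    tight_binding_warning: bool = False
    notes: list[str] = field(default_factory=list)


def _usable_kobs(fits: list[CurveFit]) -> tuple[np.ndarray, np.ndarray]:
    pts = [
        (f.inhibitor_conc, f.kobs)
        for f in fits
        if f.identifiable and f.inhibitor_conc > 0 and math.isfinite(f.kobs)
    ]
    pts.sort()
    if not pts:
        return np.empty(0), np.empty(0)
    conc, kobs = map(np.asarray, zip(*pts))
    return conc.astype(float), kobs.astype(float)


def estimate_kapp(fits: list[CurveFit], alpha: float = 0.05) -> KappEstimate:
    """Apparent second-order rate constant from kobs versus [I].

    Requires >= 3 identifiable fits at distinct positive concentrations;
    otherwise the estimate is not determinable (the panel's "*" case).
    """
    conc, kobs = _usable_kobs(fits)
    n = len(np.unique(conc))
    if n < 3:
        return KappEstimate(
            k_app=math.nan, se=math.nan, linear_region=(), saturating=False,
            K1_prime=math.nan, n_points=int(conc.size),
            note="fewer than 3 identifiable concentrations; not determinable",
        )

    # straight line kobs = b0 + b1*[I]
    lin = stats.linregress(conc, kobs)
    pred_l = lin.intercept + lin.slope * conc
    rss_line = float(np.sum((kobs - pred_l) ** 2))

    # saturation model kobs = c0 + a*[I]/([I]+K)
    def resid(p):
        c0, a, logK = p
        K = math.exp(logK)
        return c0 + a * conc / (conc + K) - kobs

    span = float(np.ptp(kobs)) or float(np.max(kobs)) or 1.0
    x0 = np.array([max(float(np.min(kobs)), 0.0), span, math.log(float(np.median(conc)))])
    sat = least_squares(resid, x0, method="lm", max_nfev=2000)
    rss_sat = float(2.0 * sat.cost)

    scale = float(kobs @ kobs) + 1e-300
    saturating = False
    if conc.size > 3 and rss_line / scale > 1e-20 and rss_sat < rss_line:
        f_stat = (rss_line - rss_sat) / (rss_sat / (conc.size - 3) + 1e-300)
        p_val = float(stats.f.sf(f_stat, 1, conc.size - 3))
        saturating = p_val < alpha

    if saturating:
        c0, a, logK = sat.x
        K1_prime = math.exp(logK)
        k_app_uM = a / K1_prime  # tangent at the origin
        # delta-method SE of a/K from the saturation-fit covariance
        se = math.nan
        dof = conc.size - 3
        if dof > 0:
            try:
                cov = np.linalg.inv(sat.jac.T @ sat.jac) * rss_sat / dof
                grad = np.array([0.0, 1.0 / K1_prime, -a / K1_prime])  # d/d(c0,a,logK)
                se = float(np.sqrt(grad @ cov @ grad)) * 1e6
            except np.linalg.LinAlgError:
                pass
        region = tuple(float(c) for c in conc if c <= K1_prime / 3.0)
        return KappEstimate(
            k_app=k_app_uM * 1e6, se=se, linear_region=region, saturating=True,
            K1_prime=float(K1_prime), n_points=int(conc.size),
            note="saturating kobs; k_app from tangent at origin of the hyperbola",
        )
    if lin.slope <= 0:
        return KappEstimate(
            k_app=math.nan, se=math.nan, linear_region=(), saturating=False,
            K1_prime=math.nan, n_points=int(conc.size),
            note="kobs does not increase with [I]; not determinable",
        )
    return KappEstimate(
        k_app=float(lin.slope) * 1e6, se=float(lin.stderr) * 1e6,
        linear_region=tuple(float(c) for c in conc), saturating=False,
        K1_prime=math.nan, n_points=int(conc.size),
    )


def correct_for_substrate(k_app: float, assay: EnzymeAssay) -> float:
    """k_true = k_app·(1 + S0/Km): undo competitive substrate protection."""
    if not k_app >= 0:
        raise ConfigError(f"k_app must be >= 0, got {k_app}")
    if assay.Km <= 0:
        raise ConfigError("Km must be > 0")
    return k_app * assay.competition_factor


def _fit_hyperbola(
    conc: np.ndarray,
    ratios: np.ndarray,
    K_init: float,
    ratio_se: np.ndarray | None = None,
):
    """Least-squares fit of ratio = 1/(1+[I]/K); returns (K, se).

    When every point carries a finite positive standard error the fit is
    inverse-SE weighted, which keeps poorly determined velocities (e.g.
    barely resolved transitions at the edges of the series) from
    dominating the equilibrium constant.
    """
    w = np.ones_like(ratios)
    if ratio_se is not None:
        se = np.asarray(ratio_se, dtype=float)
        if np.all(np.isfinite(se)) and np.all(se > 0):
            w = 1.0 / np.clip(se, np.max(se) * 1e-3, None)
            w /= np.mean(w)

    def resid(p):
        return w * (1.0 / (1.0 + conc / math.exp(p[0])) - ratios)

    res = least_squares(resid, np.array([math.log(K_init)]), method="lm", max_nfev=2000)
    K = math.exp(res.x[0])
    se = math.nan
    dof = conc.size - 1
    if dof > 0:
        rss = float(2.0 * res.cost)
        jtj = float((res.jac.T @ res.jac).item())
        if jtj > 0:
            se = K * math.sqrt(rss / dof / jtj)
    return float(K), se


def _pointwise_K(conc: np.ndarray, ratios: np.ndarray):
    vals = [c / (1.0 / r - 1.0) for c, r in zip(conc, ratios) if 0 < r < 1]
    if not vals:
        return math.nan, math.nan
    vals = np.asarray(vals)
    se = float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else math.nan
    return float(np.mean(vals)), se


def single_point_K(inhibitor_conc: float, ratio: float) -> float:
    """Invert ratio = 1/(1+[I]/K) at a single concentration."""
    if not (0 < ratio < 1):
        raise FitError(f"velocity ratio must be in (0, 1), got {ratio}")
    return inhibitor_conc / (1.0 / ratio - 1.0)


def estimate_equilibrium_constants(
    fits: list[CurveFit],
    v0: float,
    method: str = "global",
    zero_threshold: float = IRREVERSIBILITY_THRESHOLD,
) -> EquilibriumEstimate:
    """Apparent K1 (from v_i/v0) and KI* (from v_s/v0) across a series.

    ``method="global"`` fits each hyperbola across all concentrations;
    ``method="pointwise"`` inverts every concentration separately and
    averages. KI* is undefined (nan) when every steady-state velocity is
    consistent with zero — the irreversible case.
    """
    if method not in ("global", "pointwise"):
        raise ConfigError(f"unknown method {method!r}")
    if not v0 > 0:
        raise ConfigError(f"v0 must be > 0, got {v0}")
    usable = [f for f in fits if f.inhibitor_conc > 0]
    # prefer fits whose exponential transition was resolved: their v_i and
    # v_s are meaningful; fall back to the full set only if too few remain
    resolved = [f for f in usable if f.identifiable]
    if len(resolved) >= 3:
        usable = resolved
    pts = sorted((f.inhibitor_conc, f.v_i, f.v_s, f.se_vi, f.se_vs) for f in usable)
    if len(pts) < 3:
        raise FitError("need >= 3 concentrations with fitted velocities")
    conc = np.array([p[0] for p in pts])
    ri = np.array([p[1] for p in pts]) / v0
    rs = np.array([p[2] for p in pts]) / v0
    se_ri = np.array([p[3] for p in pts]) / v0
    se_rs = np.array([p[4] for p in pts]) / v0
    note = ""

    # K1 from initial velocities
    if np.all(ri >= 1.0):
        K1, K1_se = math.nan, math.nan
        note = "v_i >= v0 at every concentration; K1 undefined"
    else:
        init_vals = [c / (1.0 / r - 1.0) for c, r in zip(conc, ri) if 0 < r < 1]
        K_init = float(np.median(init_vals)) if init_vals else float(np.median(conc))
        if method == "global":
            K1, K1_se = _fit_hyperbola(conc, np.clip(ri, 0.0, None), K_init, se_ri)
        else:
            K1, K1_se = _pointwise_K(conc, ri)

    # KI* from steady-state velocities
    if np.all(rs < zero_threshold):
        KIstar, KIstar_se = math.nan, math.nan
        note = (note + "; " if note else "") + "all v_s ~ 0; KI* undefined (irreversible)"
    else:
        init_vals = [c / (1.0 / r - 1.0) for c, r in zip(conc, rs) if 0 < r < 1]
        K_init = float(np.median(init_vals)) if init_vals else float(np.median(conc))
        if method == "global":
            KIstar, KIstar_se = _fit_hyperbola(conc, np.clip(rs, 0.0, None), K_init, se_rs)
        else:
            KIstar, KIstar_se = _pointwise_K(conc, rs)

    return EquilibriumEstimate(
        K1=K1, K1_se=K1_se, KIstar=KIstar, KIstar_se=KIstar_se,
        method=method, note=note,
    )


def classify_mechanism(
    fits: list[CurveFit],
    v0: float,
    jump=None,
    theta: float = IRREVERSIBILITY_THRESHOLD,
) -> str:
    """Irreversible versus reversible slow binding from steady-state velocities.

    Irreversible: v_s/v0 < theta at every inhibitor concentration.
    Reversible slow binding: v_s/v0 >= theta for at least half the series
    and declining with [I]. Anything else is not determinable. A supplied
    jump-dilution result overrides the progress-curve call on conflict.
    """
    series = sorted(
        (f.inhibitor_conc, f.v_s / v0) for f in fits if f.inhibitor_conc > 0
    )
    if len(series) < 2:
        raise FitError("need >= 2 fits at positive inhibitor concentrations")
    conc = np.array([s[0] for s in series])
    ratios = np.array([s[1] for s in series])

    if np.all(ratios < theta):
        call = MECHANISM_IRREVERSIBLE
    else:
        enough = np.count_nonzero(ratios >= theta) >= 0.5 * ratios.size
        slope = theilslopes_safe(conc, ratios)
        call = MECHANISM_REVERSIBLE if (enough and slope < 0) else MECHANISM_UNDETERMINED

    if jump is not None:
        jump_call = (
            MECHANISM_IRREVERSIBLE if jump.recovery == "none" else MECHANISM_REVERSIBLE
        )
        if jump_call != call:
            call = jump_call
    return call


def theilslopes_safe(x: np.ndarray, y: np.ndarray) -> float:
    from scipy.stats import theilslopes

    if np.unique(x).size < 2:
        return 0.0
    return float(theilslopes(y, x)[0])


def ic50_from_inactivation(k_true: float, t_pre: float) -> float:
    """Predicted preincubation IC50 (μM) for a pure pseudo-first-order
    inactivator: IC50 = ln2 / (k_true·t_pre), with k_true in M⁻¹ s⁻¹.

    A closed-form prediction that holds when the inhibitor is in excess
    and inactivation is exponential over the whole preincubation.
    """
    if not (k_true > 0 and t_pre > 0):
        raise ConfigError("k_true and t_pre must be > 0")
    return math.log(2.0) / (k_true * t_pre) * 1e6


def build_rate_profile(
    compound_id: str,
    enzyme_id: str,
    fits: list[CurveFit],
    assay: EnzymeAssay,
    jump=None,
    method: str = "global",
) -> RateProfile:
    """Glue: assemble a full RateProfile from a fitted dilution series.

    The series must contain exactly one uninhibited control ([I] = 0),
    whose fitted v_i defines v0.
    """
    controls = [f for f in fits if f.inhibitor_conc == 0]
    if len(controls) != 1:
        raise FitError(
            f"{compound_id}/{enzyme_id}: series needs exactly one [I]=0 control, "
            f"found {len(controls)}"
        )
    v0 = controls[0].v_i
    inhibited = [f for f in fits if f.inhibitor_conc > 0]
    notes: list[str] = []

    kapp = estimate_kapp(inhibited)
    if kapp.note:
        notes.append(kapp.note)
    k_true = (
        correct_for_substrate(kapp.k_app, assay) if math.isfinite(kapp.k_app) else math.nan
    )

    try:
        mechanism = classify_mechanism(inhibited, v0, jump=jump)
    except FitError:
        mechanism = MECHANISM_UNDETERMINED
    if not math.isfinite(kapp.k_app):
        mechanism_note = "k_app not determinable by curve fitting"
        notes.append(mechanism_note)

    K1 = K1_se = KIstar = KIstar_se = math.nan
    try:
        eq = estimate_equilibrium_constants(inhibited, v0, method=method)
        K1, K1_se = eq.K1, eq.K1_se
        KIstar, KIstar_se = eq.KIstar, eq.KIstar_se
        if eq.note:
            notes.append(eq.note)
    except (FitError, ConfigError) as exc:
        notes.append(str(exc))
    if mechanism == MECHANISM_IRREVERSIBLE:
        KIstar, KIstar_se = math.nan, math.nan  # no steady-state complex to titrate

    min_I = min((f.inhibitor_conc for f in inhibited), default=math.nan)
    tight = bool(min_I < 10.0 * controls[0].enzyme_conc) if inhibited else False
    if tight:
        notes.append("tight-binding regime: min [I] < 10·[E]0; free-[I] depletion ignored")

    return RateProfile(
        compound_id=compound_id,
        enzyme_id=enzyme_id,
        v0=v0,
        k_app=kapp.k_app,
        k_app_se=kapp.se,
        k_true=k_true,
        K1_app=K1,
        K1_se=K1_se,
        KIstar_app=KIstar,
        KIstar_se=KIstar_se,
        mechanism=mechanism,
        linear_region=kapp.linear_region,
        n_curves=len(fits),
        tight_binding_warning=tight,
        notes=notes,
    )
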