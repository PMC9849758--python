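# Methods

## Reaction network and simulator

The simulator integrates the full mass-action network

```
E + S ⇌(k_on_S, k_off_S) ES →(kcat) E + P
E + I ⇌(k3, k4) EI ⇌(k5, k6) E*I
```

with scipy's LSODA (rtol 1e-8, atol 1e-10) from [P] = 0, sampling a
uniform grid (default 30 min, 181 points — a 10 s plate-reader
cadence). Detector signal is `a0_offset + signal_coeff·[P](t)` plus
additive i.i.d. Gaussian noise; the default noise SD is 1% of the
uninhibited 30-min dynamic range. Simulations are bitwise reproducible
given a seed. Total enzyme and total inhibitor are conserved to
relative 1e-8 along every trajectory (asserted in the test suite).

Substrate-binding microscopics are not identifiable from K_m alone, so
k_on_S is fixed at 10 μM⁻¹ s⁻¹ and k_off_S = k_on_S·K_m − kcat
(required non-negative). This reproduces K_m exactly and makes
substrate binding effectively instantaneous on the assay time scale,
which is what the steady-state analysis assumes.

Units: concentrations μM, time s, k3 in μM⁻¹ s⁻¹, first-order rates
s⁻¹. Second-order constants are converted to M⁻¹ s⁻¹ (×10⁶) only at
reporting boundaries.

### Assay conditions

Bundled panel conditions run each substrate at its K_m: trypsin-3
22.5 μM, β-tryptase 250 μM, thrombin 15 μM, uPA 80 μM (pNA
absorbance; all others AMC fluorescence), cathepsin G 130 μM,
chymotrypsin 58 μM, neutrophil elastase 500 μM. Enzyme concentration
in kinetic runs defaults to 1 nM, which keeps [I]₀ ≥ 10·[E]₀ for every
concentration grid used here; the default kcat per assay is chosen so
that the uninhibited 30-min conversion at 1 nM enzyme is ≈5%, inside
the <10%-conversion regime the integrated rate equation requires.
Signal coefficients are 1 AU/μM for AMC and 0.0105 AU/μM for pNA
(1-cm ε ≈ 10,500 M⁻¹cm⁻¹).

### Protocols

*Preincubation*: enzyme and inhibitor are integrated without substrate
for t_pre (default 900 s), substrate is then added at S0 with no
volume correction (dilution factors are modeled only where the bench
protocol prescribes them), and the measurement phase is recorded with
time zero at substrate addition.

*Jump dilution*: enzyme at 2.5× the working concentration is
preincubated with inhibitor at 10×IC50, then all species are diluted
10- or 100-fold into substrate; an identically handled inhibitor-free
control accompanies every treated trace. Noise scales with the diluted
control's dynamic range (the post-dilution signal is what the detector
reads).

## Progress-curve fitting

Each trace is fitted with
`A(t) = A0 + vs·t + (vi − vs)(1 − e^(−kobs·t))/kobs` by separable
least squares: for fixed kobs the model is linear in (A0, vs, vi−vs),
so a 50-point log-spaced kobs grid over [1e-5, 1] s⁻¹ with a linear
solve per node seeds a joint bounded refinement
(`scipy.optimize.least_squares`, v_i, v_s ≥ 0). Fitting is unweighted.
The signal is referenced to its first sample internally, which makes
the fit exactly invariant to constant offsets (A0 absorbs them).
Standard errors come from the Jacobian at the solution.

kobs is reported as *identifiable* only when all of the following
hold; otherwise the fit falls back to straight-line estimates
(v_i = v_s = slope, kobs undefined), mirroring the bench situation in
which a rate constant "cannot be determined by curve fitting":

1. the transition develops within the trace: kobs·T ≥ 0.1;
2. the exponential term reduces the residual sum of squares by ≥1%
   versus a straight line *and* is significant by extra-sum-of-squares
   F-test at α = 1e-3 (on 181-point traces a 1% rss reduction alone is
   well within noise, and ~5% of uninhibited controls would otherwise
   grow a spurious fast phase);
3. the transition is resolved by the sampling cadence: kobs·Δt ≤ 1
   (beyond that the exponential collapses into a one-interval step);
4. the exponential amplitude (v_i−v_s)/kobs exceeds 3× the residual
   SD — below that the "transition" is noise structure.

## Secondary inference

*k_app*: the saturation model kobs = c0 + k5'·[I]/([I]+K1') is fitted
to all identifiable (kobs, [I]) points and compared with a straight
line by extra-sum-of-squares F-test (α = 0.05). Without significant
curvature, k_app is the free-intercept OLS slope. With curvature,
k_app is the fitted tangent at the origin, k5'/K1' — the quantity the
"slope of the linear part" estimates; concentrations ≤ K1'/3 are
reported as the linear region. (A literal OLS slope over that region
systematically underestimates the tangent — by ~20% for points
reaching K1'/5 — because secants of a hyperbola lie below it.)
Substrate correction: k = k_app·(1+[S]/K_m). At least three
identifiable concentrations are required; otherwise the pair is
reported not determinable.

*K1 and K\*_I*: v_i/v_0 and v_s/v_0 are fitted to 1/(1+[I]/K) across
the series (v_0 is the fitted initial rate of the mandatory [I]=0
control). The fit is inverse-SE weighted when per-curve standard
errors are available: unweighted ratio-space fitting lets barely
resolved velocities at the series edges dominate and skews K1 high.
Per-concentration inversion K = [I]/(v_0/v − 1) with averaging is
available as an alternative (`method="pointwise"`); the global fit is
the default. K\*_I is undefined when every v_s is consistent with zero
(irreversible case). Identifiable per-curve fits are preferred when at
least three exist. Free-inhibitor depletion is ignored in these
hyperbolae; a tight-binding warning is raised when min [I] < 10·[E]₀.

*Mechanism call*: irreversible if v_s/v_0 < θ (default 0.05) at every
concentration; reversible slow binding if v_s/v_0 ≥ θ for at least
half the series and declines with [I] (Theil–Sen slope < 0); otherwise
not determinable. A supplied jump-dilution result overrides on
conflict. The θ threshold operationalizes "final velocity equal to
zero", which no finite-noise experiment can observe literally.

*Jump-dilution analysis*: both traces are fitted with the integrated
rate equation; recovery is *none* when the treated instantaneous rate
is flat and near zero (|v_s−v_i|/v_0 < 0.05 and v_s/v_0 < 0.05),
*full* when v_s reaches within 20% of the control rate, else
*partial*; the treated trace's kobs is the apparent recovery rate
(k6 plus a residual-association term).

*IC50*: three-concentration triage (10, 1, 0.1 μM) reports ">10" for
compounds not reaching 50% inhibition at 10 μM (boundary inclusive).
Full titrations are fitted with the four-parameter logistic,
unconstrained asymptotes, initialized at top = max, bottom = min,
ic50 = geometric middle, hill = 1; residual activity is the fitted
v_i of the post-preincubation trace relative to the preincubated
control (for slow binders the rate drifts during the readout, so a
30-min average would be biased). The replicate rule is implemented as
printed — a third experiment when SD > 3×mean — with the ratio
configurable, because at n = 2 the printed rule is unreachable
(SD = |a−b|/√2 ≤ √2·mean for positive replicates); the suite asserts
this anomaly rather than silently substituting a plausible intent
(e.g. SD > mean/3, also exposed).

## Reference round-trip studies

The `studies` module re-derives published-scale quantities from fully
simulated campaigns; generating constants are read from the bundled
panel tables.

* *Slow-tight binding* (apparent K1 = 15.8 μM, K\*_I = 1.11 μM on
  β-tryptase): intrinsic constants are the apparent ones divided by
  (1+[S]/K_m) = 2; k3 = 1 μM⁻¹ s⁻¹ keeps the first step in rapid
  equilibrium; k5 = 1e-2 s⁻¹ places kobs·T between ≈4 and 16 over the
  7-concentration grid (0.2×–5×K1), so every curve reaches steady
  state within the 30-min window — with slower isomerization the
  lowest concentrations sit in the flat-likelihood regime where
  (v_s, kobs) are jointly unidentifiable at 1% noise. 20 replicates,
  medians reported.
* *Irreversible binder* (apparent k_app = 7.5×10³ M⁻¹ s⁻¹ on
  β-tryptase): K1' fixed at 20 μM, concentrations 0.25–1.2 μM — low
  enough (≤K1'/16) that kobs is essentially linear in [I], high enough
  that kobs·T ≥ 3 everywhere.
* *Preincubation IC50* (0.02 μM on β-tryptase): one-step inactivator
  with k3 = ln2/(IC50·t_pre); 8 log-spaced concentrations spanning 50×
  on each side of the target at 2% noise. The wide span matters: the
  4PL's top asymptote is weakly anchored on survival-shaped data, and
  narrow (10–16×) designs bias the fitted IC50 by +6–11% even without
  noise, versus ±2% at 40–60×.

## What the synthetic data does and does not emulate

The generator reproduces the statistical structure the analysis
assumes: mass-action competition kinetics, linear detection with
additive i.i.d. Gaussian noise, uniform sampling, pseudo-first-order
design, low substrate conversion. It does **not** model signal drift
or photobleaching, inner-filter effects, enzyme autolysis or thermal
inactivation, pipetting/volume errors, well-to-well calibration
spread, or substrate depletion beyond what the network itself
produces. Passing round-trip tests therefore demonstrates estimator
correctness and robustness to detection noise under valid assay
design — not robustness to systematic artifacts of real plates, which
must still be controlled at the bench.

## Numerical choices and degenerate inputs

* Closed-form kobs uses the rapid-equilibrium hyperbola. Its validity
  requires k5+k6 ≪ k3[I]+k4; when the first step is slow (e.g.
  k3[I]+k4 only ~20× the isomerization rate) traces relax at the exact
  slow eigenvalue of the linearized three-state chain, a few percent
  below the hyperbola, and the fitted kobs tracks the eigenvalue. The
  oracle test generator draws mechanisms with a fast first step.
* The reduced integrated-rate-equation model reproduces full
  mass-action traces to <1% of the dynamic range only while substrate
  depletion is small; at 10% conversion the Michaelis–Menten rate
  itself drifts ~5%. Oracle draws keep inhibited-trace conversion ≲2%.
* Negative intermediate rate estimates are clipped at zero via fit
  bounds and noted. Exactly linear traces return slope estimates with
  kobs undefined. 4PL fits on data that never cross 50% return an
  infinite IC50 with a no-inhibition flag rather than an extrapolated
  number. Rendering uses two significant figures in text tables and
  full precision in the JSON twin.

## Known limitations

Reversible-covalent versus non-covalent slow binding cannot be
distinguished from these experiments alone. Global multi-curve fitting
of microscopic rate constants, Bayesian uncertainty, and tight-binding
(Morrison-type) corrections for inhibitor depletion are out of scope;
the tight-binding warning flags the regime where the last of these
would matter. k_app from strongly saturating series is reported as the
origin tangent with a correspondingly large standard error; designs
intended to measure k_app should stay below ~K1'/3.
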