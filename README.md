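# slowbind

Kinetic analysis of slow-binding and irreversible inhibition of serine
proteases from continuous (plate-reader) assays — the workflow used to
characterize covalent activity-based probes and slow-tight-binding
inhibitors against trypsin-like proteases (trypsin-3, β-tryptase,
thrombin, uPA, cathepsin G, chymotrypsin, neutrophil elastase).

It is written for medicinal chemists and enzymologists who record
pNA/AMC substrate-hydrolysis progress curves and need, per
compound–enzyme pair: the observed rate constant k_obs per curve, the
apparent second-order rate constant k_app, apparent equilibrium
constants K1 and K\*_I, a reversible-versus-irreversible mechanism
call, preincubation IC50s, and jump-dilution reversibility analysis —
plus a mechanistic simulator that generates synthetic assay data with
known ground truth for validating all of the above.

## The model

A probe I binds enzyme E in competition with substrate S (run at
[S] = K_m in the bundled panel conditions):

```
E + S ⇌ ES → E + P            (Michaelis–Menten turnover)
E + I ⇌(k3,k4) EI ⇌(k5,k6) E*I (one- or two-step, k6=0 if irreversible)
```

Under pseudo-first-order conditions ([I]₀ ≫ [E]₀, <10% substrate
conversion) each progress curve follows the integrated slow-binding
rate equation

```
A(t) = A0 + vs·t + (vi − vs)·(1 − e^(−kobs·t)) / kobs
```

with initial velocity v_i, steady-state velocity v_s, and

```
kobs = k6 + k5·[I] / ([I] + K1·(1 + [S]/Km))     (two-step)
kobs = k3·[I] / (1 + [S]/Km)                     (one-step)
```

Across an inhibitor dilution series,

* k_app is the slope of the linear part of k_obs vs [I]
  (k = k_app·(1+[S]/K_m) after substrate correction),
* v_i/v_0 = 1/(1+[I]/K1) gives the apparent first-step constant K1,
* v_s/v_0 = 1/(1+[I]/K\*_I) gives the apparent overall constant K\*_I
  (undefined for irreversible binders, whose v_s → 0),
* the mechanism call is irreversible when v_s/v_0 < 0.05 at every [I],
  reversible slow binding when a declining non-zero v_s persists, and
  a jump-dilution experiment (preincubate at 10×IC50, dilute 10- or
  100-fold into substrate, watch for activity recovery) overrides the
  progress-curve call on conflict.

Preincubation IC50s (activity halved after 15 min enzyme–inhibitor
incubation) are fitted with the four-parameter logistic; for a pure
one-step inactivator IC50 = ln2/(k·t_pre).

## Worked example

Simulate a slow-tight binder on β-tryptase whose apparent constants
are K1 = 15.8 μM and K\*_I = 1.11 μM, run the full analysis, and
compare what comes back:

```python
import numpy as np
from slowbind import DEFAULT_ASSAYS
from slowbind.studies import reversible_truth
from slowbind.protocols import run_inhibition_series

assay = DEFAULT_ASSAYS["beta_tryptase"]          # Km = S0 = 250 uM, AMC
truth = reversible_truth(K1_app=15.8, KIstar_app=1.11, assay=assay)
concs = np.geomspace(3.16, 79.0, 7)              # 0.2x .. 5x K1
profile, fits = run_inhibition_series(truth, assay, concs,
                                      seed=11, compound_id="probe-A")
print(profile.mechanism)
print(profile.K1_app, profile.KIstar_app)
```

prints

```
mechanism: reversible_slow_binding
k_app  = 126 +/- 115 M^-1 s^-1
k_true = 251 M^-1 s^-1
K1     = 15.76 +/- 3.80 uM
KI*    = 1.100 +/- 0.026 uM
```

i.e. from eight noisy simulated traces (one uninhibited control plus
seven concentrations at 1% detection noise) the analysis recovers the
generating constants — K1 within 0.3% and K\*_I within 1% here — and
correctly labels the mechanism reversible slow binding. The k_app of a
strongly saturating series like this one is small and poorly
determined (its standard error says so); for covalent probes, whose
k_obs stays linear in [I], it is the headline potency metric.

The same library surface is exposed as a CLI:

```
slowbind simulate --mechanism two_step_irreversible --k3 1 --k4 10 \
    --k5 0.15 --inhibitor-series 0,0.3,0.5,0.8,1.2 --seed 4 --out traces.csv
slowbind fit --traces traces.csv --out fits.csv
slowbind kinetics --traces traces.csv --compound-id demo --out profile.json
```

## Layout

| module | contents |
| --- | --- |
| `slowbind.assays` | assay conditions (Km, [S], kcat, detection), bundled panel defaults, YAML configs |
| `slowbind.mechanism` | mechanism ground truth, closed-form k_obs/v_i/v_s |
| `slowbind.simulate` | mass-action ODE simulator, preincubation and jump-dilution protocols, benchmark/oracle generators |
| `slowbind.progress` | separable fit of the integrated rate equation, identifiability flags |
| `slowbind.kinetics` | k_app, substrate correction, K1/K\*_I, mechanism classification |
| `slowbind.doseresponse` | triage, 4PL IC50, replicate rules, jump-dilution analysis |
| `slowbind.panel` | selectivity folds, activity-unit calibration, panel rendering |
| `slowbind.studies` | reference simulate-fit-infer round-trip studies |
| `slowbind.cli` | `slowbind simulate | fit | kinetics | ic50 | jumpdilute | panel` |

See `docs/methods.md` for the modeling assumptions, parameter choices
and known limitations.
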