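# imkdose

Integrated microdosimetric-kinetic (IMK) analysis of radiation dose-rate
effects on DNA double-strand breaks (DSBs) and clonogenic cell survival.

The package is for radiobiologists and modellers who ask how the *same*
absorbed dose changes its biological effect when delivery is stretched from
seconds to many hours — the central question for protracted occupational or
therapeutic exposure of normal tissue such as the lens epithelium. It
implements, as a tested Python library:

- piecewise-constant **dose schedules** (acute pulses, fraction trains,
  continuous exposure) on one absolute clock;
- the deterministic **lesion-kinetics engine**: expected potentially lethal
  lesions (PLLs), lethal lesions (LLs) and the γ-H2AX focus observable
  δ_N(t) = ⟨PLL⟩ + ⟨LL⟩ for any schedule;
- closed-form **survival** with the Lea–Catcheside dose-protraction factor;
- the four-step **parameter-estimation** chain: exponential repair fit →
  random-walk Metropolis MCMC on the survival curve → algebraic inversion to
  the microscopic rates with error propagation;
- **synthetic assay generators** (Poisson focus counts, binomial clonogenic
  colonies) so every stage runs and is testable without laboratory data;
- a **pipeline** that calibrates on acute data, predicts dose-rate
  dependence, compares observed with predicted counts (Scheffé and paired-t
  flags), and writes report tables.

## Model

The nucleus is divided into micron-scale domains in which radiation deposits
specific energy discontinuously. Reparable PLLs are produced at `k_N` per Gy
and removed first-order at rate `a + c` (repair `c`, conversion to a lethal
lesion `a`); pairs of PLLs interact second-order at rate `b`. For a
piecewise-constant dose rate `Ḋ(t)` the expected PLLs per nucleus are

    X(t) = k_N ∫₀ᵗ Ḋ(u) e^{−(a+c)(t−u)} du,

and lethal lesions accrue as

    w(t) = ∫₀ᵗ [ a·X + b·X² + γ·b·k_N²·G ] ds,
    G(t) = ∫₀ᵗ Ḋ(u) e^{−2(a+c)(t−u)} du,

where `γ = y_D/(ρπr_d²)` is the dose-mean specific energy per event
(single-track PLL pairs). With Poisson statistics for lethal lesions,
survival after a constant-rate exposure of dose `D` over time `T` is

    −ln S = (α₀ + γβ₀)·D + F·β₀·D²,
    F = 2[(a+c)T + e^{−(a+c)T} − 1] / ((a+c)T)²,

with `α₀ = a·k_N/(a+c)` and `β₀ = b·k_N²/(2(a+c))`. `F` is the
Lea–Catcheside factor: 1 for an acute pulse, →0 for very slow delivery, and
it spares only the inter-track quadratic term. The γ-H2AX focus count
tracks δ_N(t) = X(t) + w(t).

All integrals are evaluated with exact per-segment closed forms (the
integrands are sums of exponentials between segment boundaries); an
adaptive-quadrature route is kept as an independent cross-check.

## Worked example

`examples/03_survival_dose_rate.py` prints the model's dose-rate dependence
of survival for human lens epithelial cells (HLEC) with the packaged
reference parameters:

```
HLEC:
   rate (Gy/min)       F   S(2 Gy)   S(4 Gy)
         1.82000  0.9981    0.2949    0.0756
         0.10000  0.9665    0.2955    0.0770
         0.03300  0.9036    0.2968    0.0795
         0.00461  0.5374    0.3045    0.0907
         0.00081  0.1449    0.3130    0.0979
```

Between 1.82 and 0.033 Gy/min the protraction factor stays above 0.9 and
survival at 2 Gy moves by less than 0.02 — essentially no dose-rate effect —
while the multi-hour continuous deliveries visibly spare quadratic damage.
The other examples build schedules (`01`), tabulate focus kinetics for acute
vs protracted delivery (`02`), run the full synthetic-data calibration
pipeline (`04`), and null-calibrate the observed/predicted comparison
machinery across all five regimens (`05`); each script prints the numbers it
computes together with a short interpretation.

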