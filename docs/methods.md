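# Methods

## Model and assumptions

The analysis rests on the microdosimetric-kinetic picture of cell killing.
The nucleus is partitioned into `p` spherical domains (radius 0.5 μm,
water-equivalent density) over which specific energy is scored. Radiation
creates potentially lethal lesions (PLLs) in proportion to dose; a PLL can
be repaired (rate `c`, h⁻¹), convert spontaneously to a lethal lesion (LL)
(rate `a`, h⁻¹), or pair with another PLL to form an LL (nucleus-level rate
`b = b_d/p`, h⁻¹). At the nucleus level the expected PLL count under a
piecewise-constant dose-rate history Ḋ(t) is the convolution
`X(t) = k_N ∫ Ḋ(u) e^{−(a+c)(t−u)} du`, with `k_N` the initial DSB yield
per Gy. LLs accrue through three channels:

- first-order conversion `a·X(s)`;
- inter-track pairing `b·X(s)²` (PLLs from independent events);
- intra-track pairing `γ·b·k_N²·G(s)`, where
  `G(t) = ∫ Ḋ(u) e^{−2(a+c)(t−u)} du` and `γ = y_D/(ρπr_d²)` converts the
  dose-mean lineal energy of the beam into the mean single-event specific
  energy (0.954 Gy for the 150 kVp X-ray reference beam).

The kernel `e^{−2(a+c)(t−u)}` expresses that a same-event PLL pair is born
at one instant and both partners decay together; its integral to infinity
is exactly `D/(2(a+c))`, so the intra-track channel contributes exactly the
unprotracted `γβ₀D` of the closed-form survival expression for *every*
schedule. This choice resolves an ambiguity in the time-resolved formula
(as sometimes written, the protraction factor appears inside the
single-event term, and one post-exposure exponent reads `(t+T)` where the
continuous-limit kinetics require `(t−T)`): the closed-form survival
expression is taken as authoritative, because co-temporal pairs cannot be
spared by protraction, and the `(t+T)` form would make the post-exposure
lesion count discontinuous. The time-resolved lesion integral runs to `t`,
not to infinity; infinity applies only to plateau/survival quantities.

Survival assumes Poisson-distributed LLs: `S = e^{−w(∞)}`, giving the
linear-quadratic form `−ln S = (α₀+γβ₀)D + F·β₀D²` with the Lea–Catcheside
factor `F` computed from the full `a+c` (the common `a+c ≈ c` shortcut is
never used in code paths; with `a` under 2% of `c` for these cell lines the
difference is cosmetic, but exactness is free).

The γ-H2AX observable is δ_N(t) = X(t) + w(t): foci mark both unrepaired
PLLs and the lethal lesions left behind. Immediately after an acute dose
δ_N ≈ k_N·D (initial DSB yield); at late times it approaches the residual
plateau w(∞).

## Numerical choices

For piecewise-constant schedules, X and G are `A + B·e^{−λs}` on every
inter-boundary interval, so `w(t)` is integrated *exactly*: the first-order
and intra-track channels have global closed forms
(`∫X = (k_N·D(t) − X(t))/(a+c)`, `∫G = (D(t) − G(t))/(2(a+c))`) and the
`X²` channel is accumulated interval by interval. Adaptive quadrature
(abstol 1e−10, split at every segment boundary since the integrand is only
piecewise-smooth) is retained as an independent route and must agree with
the analytic one to 1e−6 relative; the test suite enforces this for both
cell lines across delivery times from 1 s to 20.6 h. The Lea–Catcheside
factor switches to its series `1 − x/3 + x²/12` below `x = (a+c)T = 1e−4`,
making `F(0) = 1` exact. Degenerate schedules (zero dose or duration) are
rejected at construction rather than silently tolerated.

Fraction "interval" is start-to-start: only this convention makes the
0.2 Gy/120 s and 0.05 Gy/90 s trains average 0.1 and 0.033 Gy/min, and the
quoted average uses the nominal cycle span `n × interval` (a
first-start-to-last-end option is provided). Internally everything is hours
and Gy/h; constructors accept Gy/min.

## Parameter estimation

Calibration uses acute-exposure data only, in four steps (the
microdosimetric `γ` is a configuration input — it comes from track-structure
simulation, which is out of scope here):

1. **Repair fit.** Nonlinear least squares of `A·e^{−ct}` to mean focus
   counts vs absolute time (scipy `curve_fit`); `k_N = A/dose`; SDs from
   the fit covariance. The 0 Gy control mean is subtracted as background
   before fitting.
2. **Survival fit.** Random-walk Metropolis over θ = (α₀, β₀, a+c) with a
   Gaussian likelihood on −ln S. Priors: uniform α₀ ∈ (0, 5) Gy⁻¹ and
   β₀ ∈ (0, 1) Gy⁻² (bounds are a documented default — wide enough to be
   uninformative for mammalian photon response); a+c Gaussian centered on
   the step-1 `c` with its fit SD, truncated to positives, so the repair
   rate acts as prior information but is updated by the survival data.
   Defaults: 10³ burn-in, 10⁴ retained samples, per-parameter Gaussian
   proposals adapted toward 20–45% acceptance during burn-in only (then
   frozen, preserving ergodicity), chain start from a crude degree-1
   polynomial fit of `−ln S / D` vs `D`, single integer seed controlling
   the whole chain. Summaries are the sample mean and SD.
3. **Likelihood width σ.** Not a measured quantity; a policy object picks
   per-point experimental SE of −ln S (`se`, the default when the table
   carries SEs), a fixed constant (0.1), or σ sampled as a nuisance with a
   Jeffreys-like 1/σ prior. The mode in force is recorded in the output.
4. **Inversion.** `a = α₀(a+c)/k_N`, `b = 2β₀(a+c)/k_N²` on the posterior
   means, with first-order (delta-method) SDs assuming independent inputs.
   The forward and inverse maps are exact mutual inverses (property-tested).

Uncertainty bands on predictions are central 68.3% posterior-predictive
percentiles over (thinned) samples rather than first-order propagation:
exact under the sampled posterior and no heavier to compute.

## Synthetic data

The generators define the study conditions under which the pipeline is
exercised: five regimens (acute 1.82 Gy/min; 0.2 Gy fractions/120 s;
0.05 Gy fractions/90 s; continuous 0.00461 and 0.00081 Gy/min), default
total dose 1 Gy (configurable; this makes the slowest delivery ~20.6 h,
leaving ~3.4 h before the 24 h observation), timepoints 0.5 and 1 h after
the end plus 24 and 48 h after the start of irradiation, ~100 nuclei per
timepoint.

Focus counts are Poisson around λ₀ + δ_N(t) with background λ₀ = 0.5
foci/nucleus by default (non-zero controls are realistic; the exact value
is a convention and is configurable); a negative-binomial overdispersion
knob (default off) acknowledges that real focus distributions are often
wider than Poisson. Colony counts are Binomial(n_plated, pe₀·S) with the
dose-tiered plating design (10³ cells at 0 Gy, 3·10³ at 2 and 4 Gy, 5·10³
at 6 Gy, 10⁴ at 10 Gy) and pe₀ = 0.3 (not critical: the plating efficiency
cancels from the surviving fraction in expectation). A flask with zero
colonies yields no measurable surviving fraction and is recorded as
missing, exactly as a bench analysis would exclude it; at 10 Gy with these
parameters this is common (~1.7 expected colonies), and fits simply use
the remaining flasks. A lognormal-noise variant (`gen_survival_lognormal`,
cv 10%) provides the idealized noise model used in parameter-recovery
studies.

What passing tests show — and do not show. Because the generators draw from
the model itself, recovery and null-calibration tests validate the
*machinery*: the estimators are consistent, the chain is ergodic and
deterministic under seed, and the comparison step manufactures no spurious
dose-rate structure (observed/predicted ratios within 3 SE of 1 at every
regimen). They cannot certify the model against real biology; in particular
the reported inverse dose-rate effect in real residual-focus data (late
counts up to ~2–2.5× model prediction at the lowest rate) is deliberately
*not* reproduced by the generators, so that any such excess seen through
this pipeline is attributable to the data.

## Problem sizes

Defaults were chosen as the smallest sizes at which the statistical checks
are stable: 10³/10⁴ MCMC burn-in/samples per chain, 20 seeds for coverage
(≥18/20 within 2 posterior SD), 100 nuclei × 4–6 timepoints for focus
tables, 3 clonogenic replicates, 200 replicates for significance-flag
calibration. A full suite run takes well under a minute on one CPU.

## Known limitations

- Only the scalar `γ` carries beam quality; LET spectra, per-domain
  stochastics, cell-cycle redistribution during exposure, bystander
  signalling and oxygen effects are out of scope.
- One `γ` serves all regimens by default; a per-schedule override exists
  for sensitivity analyses (e.g. the slightly lower DSB yield of γ-rays
  vs X-rays) but no automatic correction is applied.
- The repair fit assumes a single-exponential decay; fast phosphorylation
  kinetics within the first half hour are not modelled.
- Single-chain sampling with frozen post-burn-in steps; no R-hat style
  multi-chain diagnostics.
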