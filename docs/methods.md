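# Methods

## The detection model

`nocifit` models the probability that a human observer detects a low-
intensity electrocutaneous pulse train delivered through an intra-epidermal
electrode. A stimulus is described by four controllable properties: the
current amplitude `A` (mA), the number of pulses `NoP`, the inter-pulse
interval `IPI` (ms, absent for a single pulse) and the pulse width `PW`
(ms). The mechanistic cascade is:

1. **Peripheral activation.** The afferent-fibre membrane charges
   exponentially during a pulse, so the effective drive is
   `fA = A (1 − exp(−PW/τ₁))` with the peripheral time constant `τ₁` (ms).
   Activation passes a threshold-linear gate, `c = [fA − α₁]₊`, with
   peripheral threshold `α₁` (mA).
2. **Synaptic current.** Each pulse onset `t_k = k·IPI` injects an
   excitatory post-synaptic current `(c/τ_s) exp(−(t−t_k)/τ_s)` with the
   fixed synaptic time constant `τ_s = 1.5` ms. Each term is gated by
   `H(t − t_k)` so that a pulse contributes only after its own onset.
3. **Central integration.** A second-order dorsal-horn neuron integrates
   the current as a leaky integrator, `τ₂ ẋ = −x + I(t)`, `x(0) = 0`. The
   exact solution is a sum of double exponentials per pulse,

   `x(t) = c Σ_k [exp(−(t−t_k)/τ₂) − exp(−(t−t_k)/τ_s)] / (τ₂ − τ_s)`,

   with the removable singularity at `τ₂ = τ_s` replaced by the analytic
   limit `c (t−t_k) exp(−(t−t_k)/τ_s)/τ_s²` when `|τ₂ − τ_s| < 10⁻⁶ τ_s`.
   The unit convention mA, ms, kHz and A/s (mA/ms ≡ A/s) keeps the cascade
   dimensionally closed.
4. **Spiking and detection.** `x(t)` drives an inhomogeneous Poisson
   process with sigmoidal rate `λ(t) = λ_L / (1 + exp((α_L − x)/σ_L))`
   (kHz), where `α_L` is the central threshold, `σ_L` the slope and `λ_L`
   the maximal rate. Detection means at least one spike in the trial
   window `[0, T]`:

   `Ψ(S; θ) = 1 − exp(−∫₀ᵀ λ(t) dt)`.

The six lumped parameters are `θ = (α₁, τ₁, τ₂, α_L, σ_L, λ_L)`. The
feasible space is a hypercube with bounds
`α₁ ∈ [10⁻⁶, 1]` mA, `τ₁ ∈ [10⁻², 3]` ms, `τ₂ ∈ [2, 10³]` ms,
`α_L ∈ [10⁻⁵, 1]` A/s, `σ_L ∈ [10⁻⁸, 0.1]` A/s, `λ_L ∈ [10⁻³, 10²]` kHz.

### Numerical evaluation of Ψ

Only the rate integral needs quadrature; `x(t)` is exact. The public
`detection_probability` uses adaptive composite Gauss–Legendre quadrature
(order 40) over one panel per inter-pulse segment plus a graded tail
ladder, bisecting panels until the coarse/fine discrepancy is below a
relative tolerance (default 1e−8); persistent disagreement raises a
quadrature error naming the offending panel. The likelihood hot path
(`LikelihoodEvaluator`) uses the same panel-bisection principle but
batched: panel integrals are evaluated for all amplitudes of a temporal
combination at once (the membrane kernel is shared), a panel being
accepted when the Richardson check passes for every amplitude (rtol
1e−7). Adaptivity in the hot path is not a luxury: for small `σ_L` the
rate is nearly a step function in time, and a fixed node layout
mis-integrates it by enough (~0.2 in NLL on a 200-trial session) to
manufacture a spurious likelihood descent toward tiny `σ_L`. The two
paths agree to ~1e−5 in NLL across the feasible space; one hot-path
evaluation costs about 1 ms on a 200-trial session.

### The trial window T

`T` is configurable (default 1000 ms). It matters in two ways: the
central response must have decayed (`T > stimulus span + 5 τ₂`, otherwise
a validation warning fires), and the spontaneous detection probability at
`A = 0` is `1 − exp(−T λ_L /(1 + exp(α_L/σ_L)))` — about 1% at the
reference parameters — so estimates of `λ_L`, `α_L`, `σ_L` depend mildly
on the chosen `T`.

## Likelihood and estimation

Trials are independent, so the dataset likelihood is a product of
Bernoulli terms `Ψ_k^{R_k} (1−Ψ_k)^{1−R_k}`. Probabilities are clamped
into `[10⁻¹², 1−10⁻¹²]` inside logarithms. The negative log-likelihood is
recast as a least-squares problem with residuals `sqrt(−log Ψ_k)` for
detections and `sqrt(−log(1−Ψ_k))` for misses (grouped per
(combination, amplitude) cell; the squared sum equals the NLL exactly)
and minimised with SciPy's trust-region-reflective solver.

All optimisation is performed in log10 parameter space: the bounds span
2–6 decades per parameter, and the log transform makes the trust region
meaningful across scales. Multi-start search draws `N_s` starting points
(default 100; scaled-down analyses use 16–20) by Latin-hypercube sampling,
also log10-uniform, with one point per marginal stratum. The estimate is
the arg-min over starts; the full per-start trace is retained so that the
sorted final NLLs can be inspected for the plateau ("step pattern") that
indicates effective local optimisation. Optimiser tolerances are 1e−10
(gradient, step and function), max 3500 residual evaluations per start.

Estimates within 10⁻³ of the log10-range of either bound are flagged as
boundary estimates; identifiability analysis of such fits is unreliable.
One caveat: whether a *flat* likelihood plateau (e.g. the non-detection
regime of an all-miss dataset) terminates on the bound or just inside it
is an optimiser detail, so boundary counts should not be over-interpreted.

### Combining repeated sessions

Two same-design sessions may be concatenated when, per combination,
(a) the amplitude ranges overlap by at least 50% of the shorter range, and
(b) at every amplitude level present in both sessions the exact
(Clopper–Pearson, 95%) binomial intervals of the detection fractions
overlap. These thresholds automate what was historically a visual
screen; both are configuration-exposed, and failures are returned as a
structured rejection rather than an exception.

## Baseline comparison and goodness of fit

The conventional baseline fits, per temporal combination `j`, a logistic
regression `logit Pr(R=1|A) = β₀ⱼ + β₁ⱼ A` (statsmodels GLM/IRLS). With
four combinations that is 8 coefficients versus the hazard model's 6
parameters, fixed regardless of design size. Complete separation is
detected combinatorially (an amplitude cut that classifies every
response) and handled by a bounded refit with `|β₁| ≤ 10³` per mA plus a
flag, so the BIC stays finite.

Model comparison uses `BIC = −2 log L̂ + n_P ln n_D` (natural log); on a
collection of datasets, a one-tailed exact binomial (sign) test asks
whether the hazard model achieves the smaller BIC more often than chance.
Absolute fit uses the likelihood-ratio statistic
`G² = 2(log L_saturated − log L_model)` against the saturated model whose
cell probabilities are the observed detection fractions
(`0·log 0 := 0`), on `(#cells − 6)` degrees of freedom, with cells formed
per (combination, amplitude) after rounding amplitudes to 0.01 mA.

## Identifiability analysis

### Profile likelihood

For each parameter the profile `LPL(θᵢ) = −2 log max L` (others free) is
computed on a log-spaced grid over the full feasible range (default 41
points, the estimate inserted), sweeping outward from the estimate in
both directions. Each grid point is a 5-parameter bounded re-optimisation
warm-started from (a) the neighbouring grid solution carried along the
parameter-scaling symmetry — exact at a single pulse width, an excellent
approximation otherwise, and essential because `α₁, α_L, σ_L` move
together along a sloppy valley — (b) the neighbouring solution verbatim,
and (c) the global estimate; on single-pulse-width data the closed-form
symmetry transform of the estimate provides a further, analytically exact
start, and the working estimate is first canonicalised along the
symmetry manifold (a likelihood-identical representative choice) so those
starts stay feasible across the whole `τ₁` range. If a sweep beats the
global optimum materially, the fit is re-opened: the profiler adopts the
better optimum and recomputes the curve around it (the validation role of
profiling); sub-material jitter only updates the reference value.

The 95% confidence interval is the connected sub-threshold component
(`LPL ≤ −2 log L̂ + 3.84`, the χ²(1) quantile) containing the estimate,
with endpoints interpolated linearly in `LPL` vs log10 of the parameter;
a component that runs into a feasible-space bound is an open (unbounded)
interval. Disconnected sub-threshold components are flagged multimodal.
`Profiler.confidence_interval` additionally refines closed endpoints by
Brent bisection on the profile objective, removing the interpolation
error of coarse grids (used by the recovery experiments).

Classification: a contiguous flat run (`LPL` within 0.01 of its minimum)
around the estimate spanning ≥10% of the log-range ⇒ *structurally
non-identifiable* (the flat interval's endpoint ratio is reported); an
open interval without such flatness ⇒ *practically non-identifiable*;
otherwise *identifiable*. The flatness tolerance 0.01 is far below the
3.84 CI offset; both are configuration-exposed. For acceptance-grade
measurement of the flat-interval ratio, `Profiler.flat_interval` refines
the two edges by Brent bisection on the profile objective itself, since a
41-point grid over six decades resolves ratios only to a factor ~1.4.

### The single-pulse-width symmetry

When every stimulus shares one `PW`, the likelihood is exactly invariant
under scaling `α₁, α_L, σ_L` by a common factor `r` while re-solving
`τ₁* = −PW / ln(1 − r (1 − exp(−PW/τ₁)))` (and keeping `τ₂, λ_L`): the
scaled drive and thresholds cancel inside the rate sigmoid. `τ₁` is
therefore non-identifiable over its entire range, and `α₁, α_L, σ_L` are
set-identifiable over an interval whose endpoint ratio is

`r = (1 − exp(−PW/τ₁ˡ)) / (1 − exp(−PW/τ₁ᵘ))`,

equal to 7.6545 for `PW = 0.42` ms and `τ₁ ∈ [0.01, 3]` ms; it decreases
in `PW` (towards 1) and tends to `τ₁ᵘ/τ₁ˡ = 300` as `PW → 0`. Varying the
pulse width across stimuli is therefore *necessary* for structural
identifiability; `check_design_pw_variation` screens designs for this
before any data are collected, and additionally warns when all supplied
amplitudes stay below the peripheral threshold (the trivial
over-parameterised case).

## Synthetic sessions

The generator emulates the statistical structure the analysis assumes —
not the full psychophysical protocol. A session is 200 trials (10 minutes
at the experimental pacing) split equally over a design's four temporal
combinations, interleaved round-robin. Two presets exist: `TS1`
(`NoP` 1/1/2/2, `IPI` –/–/10/50 ms, `PW` 0.42/0.84/0.42/0.42 ms) and
`TS2` (`NoP` 1/2/2/2, `IPI` –/10/50/100 ms, `PW` all 0.42 ms).
Amplitudes come from an interleaved per-combination 1-up/1-down staircase
(start 1.5 mA, step 0.1 mA, clipped to 0–3 mA), which equilibrates around
the 50%-detection amplitude — a deliberate stand-in for the richer
adaptive probing procedure used experimentally, whose rules are outside
this package's scope; a uniform-grid policy is available as an
alternative. Responses are `R = 1` when a standard-uniform draw falls
below `Ψ(S; θ_true)`. The default `θ_true` is the reference vector
`(0.1 mA, 0.1 ms, 50 ms, 0.022 A/s, 0.0021 A/s, 0.4020 kHz)`, whose
50%-detection amplitudes lie inside 0–3 mA for every preset combination.

What a green synthetic test does establish: the estimator recovers
parameters from data generated by the model itself, the profile machinery
reproduces the analytically predicted structural signatures, and the
pipeline is deterministic given a seed. What it does not establish:
robustness to model misspecification, non-stationarity (habituation),
lapses/false alarms beyond the model's spontaneous rate, or the
amplitude distributions of real adaptive procedures.

## Known limitations

- `σ_L` is only weakly identified from below by near-threshold data: even
  with `σ_L → 0` the model produces graded detection probabilities
  through the time-above-threshold Poisson mechanism
  (`λ_T ≈ λ_L · measure{t : x(t) > α_L}` varies continuously with the
  amplitude), so a 1-up/1-down staircase session — which concentrates
  trials near the 50% point and rarely samples the psychometric flanks —
  often cannot distinguish a steep sigmoid from a step. On such data the
  `σ_L` profile can be flat well below the structural
  set-identifiability window, and the maximum-likelihood `σ_L` itself may
  land orders of magnitude below the generating value at no likelihood
  cost. Amplitude placements that sample the flanks constrain `σ_L`
  much better.
- Profile curves inherit multi-start optimisation's usual caveat: a grid
  point's re-optimisation can in principle miss the constrained optimum,
  biasing `LPL` upward. Warm starts from both sweep directions, the
  estimate and the symmetry transform mitigate this.
- `T` is a modelling choice, not a measured quantity; estimates of the
  central parameters depend mildly on it through the spontaneous rate.
- Single-fibre populations, membrane noise, explicit spike trains and
  supraspinal processing are outside the model's scope.
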