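# Methods

## Current model and units

I_Kr is modelled as `g_Kr · a · r · (V − E_K)` with independent first-order
activation (`a`) and inactivation (`r`) gates whose rates are exponential
in voltage. Internally the rate equations take V in **volts** and return
rates in s⁻¹ (the slope parameters p2, p4, p6, p8 therefore carry units of
V⁻¹); every public interface speaks mV and conversion happens in exactly
one place, so a 1000× slope error cannot arise. Current follows the
convention `I [pA] = g_Kr [pS] × a r × (V − E_K) [mV] × 10⁻³`
(1 pS·mV = 10⁻³ pA). The reversal potential is never fitted; it comes from
the Nernst equation with R = 8.314 J K⁻¹ mol⁻¹ and F = 96485 C mol⁻¹. At
the default solutions (4/110 mM K⁺) and exactly 25 °C this gives
−85.15 mV; the commonly quoted −85.2 mV corresponds to a bath temperature
a fraction of a degree warmer.

The shipped reference parameter set is the room-temperature manual-patch
parameterisation of the same model (Beattie-style cell #5), converted to
the s/V convention. It is the default centre of the synthetic across-well
population.

## Staircase protocol

The calibration protocol is 15 s of steps and ramps (hardware-compatible
with plate-based patch-clamp systems): a 400 ms leak ramp from −120 to
−80 mV inside the first second (hERG is shut below −80 mV, so everything
recorded there is leak); a 1 s activation step to +40 mV followed by a
500 ms step to −120 mV whose tail serves as the leak-rectification zero
window; a main staircase of 22 steps of 500 ms each moving in 20/40 mV
increments over −120…+40 mV (up, then mirrored down — long enough at each
level to see the characteristic I_Kr decay); a final +40 mV activation
step; and a 100 ms reversal ramp starting at 14.41 s sweeping −70 to
−110 mV so the open-channel current crosses zero near E_K. The exact
per-step voltage table of the original published waveform is not public in
the main text, so the builder is fully parameterised and the default is an
approximation that honours all of the documented structural anchors
(durations, ramp placements, voltage range, holding potential −80 mV).
Sampling defaults to 10 kHz; the synthetic studies run at 2 kHz and the
inference studies at 1 kHz (desk-scale choices; the slowest inactivation
time constants are 4–10 ms, so 1 kHz still resolves them).

Simplified step/ramp templates for classical validation protocols
(activation I-V, steady-state inactivation, action-potential-like clamps
at 0.5/1/2 Hz) are provided as configurable stand-ins; they are not
reproductions of any particular instrument's waveforms.

## Simulation

Because V(t) is piecewise linear, each gate obeys a scalar linear ODE with
piecewise-smooth coefficients. The simulator advances both gates with the
exact exponential update over each sampling interval, evaluating the rates
at the interval's midpoint voltage: on constant-voltage steps this is the
analytic solution to machine precision, on ramps it is second-order
accurate, and segment discontinuities are handled exactly because the
default grids align sampling intervals with segment boundaries. The
integrator is numba-compiled; a full 15 s staircase at 2 kHz simulates in
about a millisecond, which is what makes desk-scale MCMC affordable.
Tests verify the trajectories against the closed-form mono-exponential
relaxation to better than 10⁻⁶ in gate units.

## Synthetic data generator

The generator emulates the statistical structure a plate experiment hands
to the analysis:

* per-well parameters θ_j = exp(φ_j), φ_j ~ N(μ, Σ) (multivariate
  log-normal across wells); the default Σ is diagonal with log-SD 0.3 for
  g_Kr and 0.15 for the kinetic parameters;
* paired sweeps: two control sweeps containing I_Kr + endogenous
  background + linear leak, and two blocker sweeps containing background +
  a *different* linear leak (leak drifts between recordings); full hERG
  block is assumed;
* i.i.d. Gaussian noise, fresh per sweep; designed-pass wells draw
  σ_j log-uniformly from 0.8–2.5 pA, a band chosen (from the QC formulas,
  before any verdicts were evaluated) so that passing wells clear the QC2
  SNR threshold of 25 and the QC3 stability bound with a comfortable
  margin while the blocker-sweep stability check still sees leak current
  well above the noise;
* an optional per-well voltage-clamp error ΔV_j ~ N(0, 1.5² mV²), applied
  to the voltage the channel experiences while the recorded protocol stays
  nominal (1.5 mV matches the observed spread of reversal-potential
  estimates in plate experiments);
* a small endogenous background current — a linear-above-threshold
  conductance reaching ~2% of the hERG peak at +40 mV. This is a declared
  synthetic stand-in: real endogenous currents are not characterised here,
  and the component only needs to be nonlinear in voltage yet removable by
  blocker subtraction;
* designed QC failures (a configurable fraction of wells, cycling through
  low SNR at target subtracted-SNR 5–12, an unstable second control sweep,
  a 60%-remaining weak block, and out-of-range series resistance), labelled
  in the truth manifest so QC verdicts can be checked against construction.

Not modelled, deliberately: capacitive/series-resistance transients,
current rundown (the short protocol is the argument for ignoring it),
partial-block kinetics of the blocker, and temperature dependence. Passing
tests on these data therefore demonstrate correctness of the analysis
pipeline under its own assumptions — not robustness to artefacts the
generator does not produce.

Datasets are written as plain-text per-well CSV traces plus a JSON truth
manifest; regeneration from the same seed is byte-identical.

## Preprocessing

Leak is estimated per sweep by ordinary least squares of current against
voltage over the leak ramp (g_leak = slope, E_leak = −intercept/slope) and
subtracted as `g(V − E)`; the corrected blocker sweep is subtracted from
the corrected control sweep to remove the endogenous background. On
noiseless synthetic wells this pipeline returns the model current to
10⁻⁸ pA when the true leak models are used. The *estimated*-leak path
carries a small, well-understood bias: roughly 1 pA of hERG current flows
during the leak ramp at reference parameters, contaminating the regression
by ~0.01 nS; the recovery studies therefore follow the synthetic-study
convention of adding noise directly to the model current, and the
estimated-leak bias is tested at its realistic magnitude instead of being
hidden inside a loose tolerance.

Post-hoc rectification removes any residual linear leak `g*(V + 80 mV)` by
zeroing the mean current over a window where I_Kr should vanish; the
default window is the last 100 ms of the −120 mV step after the first
activation step (deactivation at −120 mV has τ ≈ 40 ms, so the tail has
decayed by >4 time constants there).

The reversal potential is estimated on the reversal ramp by mapping
samples to (V, I) pairs, fitting a cubic to I(V) within ±10 mV of the
observed sign change, and taking the real root nearest the crossing. Sign
convention for the clamp error: if the channel experiences V + ΔV while
the amplifier reports V, the apparent crossing sits at E_K − ΔV, so the
estimated per-well voltage error is `ΔV̂ = E_K(Nernst) − Ê_K`; this tracks
the applied offset with slope 1.0 ± 0.1 in tests.

## Quality control

QC1–QC6 follow the published battery: electrical ranges (R_seal ∈
[0.1, 1000] GΩ, C_m ∈ [1, 100] pF, R_series ∈ [1, 25] MΩ, closed
intervals); SNR = var(trace)/var(noise) > 25 on raw and subtracted traces;
sweep-pair stability RMSD < 0.2 × mean RMSD-to-zero for raw, blocker and
subtracted pairs; before/after metadata drift (two-point population
std/mean) < 0.5 strictly; ≥75% drop of max |I| over the protocol's second
half and ≥50% drop of whole-trace RMSD-to-zero after blocker; and window
means above −2× the noise SD on the three designated +40 mV steps. Where
the published table leaves a statistic unspecified the convention is
declared here: the noise level is the SD of the subtracted current over
the first 200 ms at holding; QC5 uses |·| maxima; QC4 uses the two-point
population SD; interval endpoints are inclusive and inequalities strict
exactly as printed; two identically-zero sweeps fail QC3 (a silent well is
not a stable recording). On the default seeded plate the verdicts agree
with the generator's designed pass/fail labels exactly.

## Single-well inference

The likelihood is i.i.d. Gaussian on the fitted samples. Fits use the
staircase trace from 0.9 s onward: the holding period and leak ramp carry
no kinetic information (the channel is closed) and the ramp is reserved
for leak estimation.

**Prior.** Uniform box on φ = ln θ: g_Kr ∈ [0.1, 5×10⁵] pS, rate
amplitudes ∈ [10⁻⁴, 10⁶] s⁻¹, slopes ∈ [10⁻⁴, 400] V⁻¹, intersected with
the physiological constraint that each transition rate, evaluated at its
maximally activated voltage (+60 mV for rates increasing with V, −120 mV
for decreasing), lies in [1.67×10⁻², 10⁶] s⁻¹. The constraint is one-sided
by design — at the opposite voltage extreme a rate may be arbitrarily
small, as real deactivated channels are; bounding it there would exclude
every realistic hERG parameterisation.

**Optimisation.** A self-contained CMA-ES-style evolution strategy
(rank-1 + rank-μ covariance adaptation, cumulative step-size control)
searches a unit-normalised box in which g_Kr and the amplitudes are on a
log scale and the slopes on a linear scale — the mix that makes the SSE
landscape most benign for this model class. Restarts (default 5) start
from the best of 32 prior draws; the search stage runs on a 4× coarsened
time grid (the exponential integrator stays exact on steps, so only ramp
detail is coarsened) and the best restart is polished on the full grid
with bounded L-BFGS. σ is profiled analytically as the RMS residual rather
than searched, exploiting the separability of the Gaussian scale. On
noiseless staircase data all nine parameters are recovered to better than
0.1% from prior-sampled starts; a single fit takes ~8 s at 1 kHz.

**Sampling.** Population MCMC over (φ, ln σ): several independent
replicate populations, each a geometric temperature ladder (β = 1, ½, …)
of random-walk Metropolis chains with adaptive proposals, exchanging
states between neighbouring rungs once per iteration. The proposal
covariance is initialised from a Gauss–Newton (Laplace) approximation at
the MAP — finite-difference Jacobian of the simulated current — scaled by
2.38²/d, with replicate starts overdispersed by twice the Laplace SDs.
Adaptation is vanishing (γ_t ∝ t⁻⁰·⁶) with the covariance frozen for the
first 300–500 iterations: adapting it from a barely-moved chain collapses
the proposal and stalls mixing. Convergence is summarised by split-R̂
across replicates. Defaults are 3 × 20 000 iterations with a 5-rung
ladder; the desk-scale studies use 3 × 5000 with 2 rungs, which gives
R̂ ≲ 1.1 and accurate 95% quantiles for this near-Gaussian posterior.

**What coverage can and cannot show.** The per-well posterior is tight
(relative SDs ~10⁻³) and near-Gaussian, so the frequentist behaviour of
credible intervals is governed by the Fisher-information geometry of the
protocol: estimator z-scores are MVN(0, R) with |R| entries up to ~0.9,
independent of the noise level. Failures of individual 95% intervals
therefore cluster in correlated pairs within a well. The meaningful
calibration statement at a 20-well scale is aggregate: across the 20×9
intervals of the recovery study the empirical coverage of nominal-95%
intervals exceeds 90%. A per-well statement like "≥8/9 parameters covered
in ≥90% of wells" is not a reliable diagnostic at this scale — Monte Carlo
over the exact asymptotic posterior shows even a perfect sampler satisfies
it in only ~58% of seeds — so the tests assert the aggregate form and
report the per-well fraction.

## Hierarchical model

Across wells φ_j ~ N(μ, Σ) with a conjugate normal–inverse-Wishart
hyperprior: ν₀ = 12 (dim + 3), Ψ₀ = 0.005·I on the log scale, κ₀ = 0 (no
shrinkage of μ; its prior mean then only matters as a fallback). The
pseudo-Metropolis-within-Gibbs sampler alternates (i) redrawing each φ_j
uniformly from that well's stored posterior chain — valid because the
per-well data overwhelm the hyperparameters' influence on the well-level
conditional — and (ii) conjugate draws of μ | Σ and Σ | μ. The noise
scales σ_j keep independent priors and are not pooled. With κ₀ = 0 the
marginal posterior of Σ is InvWishart(ν₀ + N − 1, Ψ₀ + S) about the
sample mean; the test suite checks the Gibbs sampler against this analytic
form directly, which separates sampler correctness from the irreducible
N-well sampling error of comparisons against the generating truth.

The synthetic recovery study draws 20 wells from a strongly correlated
truth — correlation 0.9·ss' + 0.1·I with a ±1 sign pattern s, log-SDs 0.3
(conductance) and 0.15 (kinetics) — i.e. scatter dominated by a single
latent axis, the structure a shared artefact mechanism produces. At
N = 20 the sampling SD of an empirical correlation entry is ≈0.04 at
ρ = 0.9 (versus ≈0.23 at ρ = 0), so elementwise recovery within ±0.15 is a
meaningful bound under this truth and is met, with every strong
correlation's sign recovered. The population mean μ is recovered inside
its marginal 95% intervals.

The posterior predictive for a future well is the mixture over hyper
samples of LogNormal(μ, Σ); density evaluation, marginals and sampling are
provided and tested against single-component closed forms and Monte Carlo
moments.

## Voltage-error study

To probe whether apparent well-to-well variability can be produced by
clamp offsets alone, data are simulated with the channel experiencing
V + ΔV, refitted under the nominal protocol (warm-started continuation
from the reference parameters — the perturbations are small and the
landscape smooth), and the displacement δφ(ΔV) recorded. Eight of the nine
parameters respond to ΔV with an odd-dominated, monotone displacement; the
activation slope p2 responds quadratically (an even function of ΔV) with an
order-of-magnitude smaller amplitude. The overall displacement direction is
antisymmetric to cosine < −0.9 at ±2 mV, and the reversal-ramp estimate of
ΔV tracks the applied offset 1:1. When a batch of wells differs *only* in
ΔV_j, the leading principal axis of the fitted-parameter scatter aligns
with the offset displacement direction with |cos| > 0.99 — reproducing, on
synthetic data, the signature that implicates voltage errors as a dominant
source of apparent cell-to-cell variability.

## Numerical conventions and degenerate cases

* Protocol time is 0-based and segments half-open; `voltage_at` is
  left-continuous at boundaries. Protocol files round-trip at microsecond
  / 0.001 mV precision.
* Zero-conductance leak models make E_leak unidentifiable; the estimator
  then reports g = 0 and folds any offset away. Rectification refuses
  windows where mean(V + 80 mV) = 0.
* The reversal estimator requires a sign change in the window and picks
  the polynomial root nearest the crossing.
* `draw_well_parameters` accepts the zero matrix (point mass) and rejects
  indefinite covariances; exactly singular ones get a 10⁻¹² jitter.
* RRMSE is undefined (raises) for identically zero data; percentile
  selection is nearest-rank with ties broken by well id, so panel
  summaries are deterministic.
* Trace normalisation uses the least-squares scale (closed form) by
  default with an L1 option; an exactly orthogonal trace scales to 0 with
  a warning, a zero-energy trace raises.
* All stochastic components take explicit seeds or Generators; identical
  seeds give bit-identical datasets, fits, chains and manifests on the
  same platform.

## Desk-scale problem sizes

Studies in the test suite and acceptance script are sized for a single
core: 2 kHz grids for data-facing checks, 1 kHz for inference; 16-well
plates for QC; 20 wells for the recovery and hierarchy studies with
3 × 4000–5000 MCMC iterations and a 2-rung ladder (in the reproduction
script, ten of the twenty wells carry full-length chains for the coverage
check and the rest shorter ones, which is all the hierarchy needs);
10⁴-iteration default (10⁵-capable) Gibbs chains reduced to 3000 where
they enter tests. All sizes are configuration, not constants.

## Known limitations

* The staircase default is a structurally faithful approximation, not the
  instrument-exact published waveform; absolute information content will
  differ slightly.
* The estimated-leak pipeline inherits the ~0.01 nS hERG-contamination
  bias discussed above; for very small currents this matters.
* The hierarchical sampler assumes per-well posteriors are insensitive to
  the hyperparameters (the pseudo-Gibbs approximation); it is inappropriate
  when wells carry little data.
* No modelling of capacitive transients, rundown, partial block, or
  temperature dependence; conclusions from synthetic studies extend to
  real recordings only insofar as those artefacts are removed upstream.
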