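# Methods

## Oscillator population

The biomarker model is a globally coupled Kuramoto population: N phase
oscillators with fixed angular frequencies ωᵢ and coupling γ, integrated
with explicit Euler at dt = 1 ms (configurable). The pairwise coupling sum
(γ/N)Σ sin(θⱼ−θᵢ) is evaluated in its algebraically identical mean-field
form γρ sin(ψ−θᵢ), which makes each step O(N); both forms are exposed by
`step_population` and tested for equality, and a dt-halving test bounds the
discretization error of a trial's Δρ below 10⁻².

Parameters (defaults): N = 50; f₀ = 8 Hz (tremor band); coupling γ = 0.8;
stimulation intensity I = 30. The frequency spread parameter σ = 0.0075 is
interpreted as a *fraction* of f₀ (std 0.06 Hz), with draws outside
f₀ ± 0.15 Hz redrawn rather than clamped (no boundary atoms); an absolute-σ
mode is available (`sigma_mode="absolute"`). The fractional reading is the
one under which the population settles at the expected high-synchrony
plateau: measured time-averaged ρ ≈ 0.81 over five seeds after a 200 s
burn-in, versus ρ ≈ 0.998 under the absolute reading, which would leave
essentially no partial synchrony to suppress.

## Phase-locked stimulation and the trial protocol

Stimulation perturbs every oscillator through a type-II phase response
curve Z(θ) = −sin(θ + Δθ), gated by a pulse train X(t). A pulse
(default width: one integration step) fires when the *population mean
phase* ψ comes within half an integration step of the trigger point; the
trigger point leads the target phase by half the pulse's phase extent so
the delivered pulse is centred on ψ_target. Firing on the first sample
past the crossing instead delivers the pulse on average half a step late,
which measurably skews the response curve near its zero crossings. A
refractory of half a mean period suppresses double-triggering from ψ
jitter.

One optimization step simulates `step_duration_s` seconds: an unstimulated
head (recovery + baseline), the baseline coherence averaged over
`baseline_window_s` immediately before stimulation, then pulses during the
trailing `stim_window_s`. The default protocol is 58 s / 25 s / 8 s; the
population state is carried across steps (one continuous simulation).

**Shape of the response.** A first-order expansion of the pulse's effect on
the order parameter gives Δρ per pulse ∝ cos(ψ_target)·(1 − ρ₂)
(ρ₂ the second circular moment): stimulation at the population phase
synchronizes, at antiphase desynchronizes, and the zero crossings sit at
ψ_target = ±π/2 exactly. Empirically the measured Δρ at ±π/2 is therefore
indistinguishable from the no-stimulation fluctuation floor (|Δρ| ≲ 0.03
for the reference protocol) and its sign there is not reproducible; tests
that assert a strict sign at the boundary phases fail for this structural
reason, not from an implementation defect. The ARC minimum at ψ* = −π and
the sign structure on the open half-circles are robust.

## Time-varying surrogate

Exact GP regression over (phase, step index) with zero prior mean and the
spatio-temporal kernel K̃ = K_s ∘ K_t:

* spatial: exponential-sine-squared with period T_x = 2π (forced by the
  phase space) and lengthscale l_x (default 1.0 rad — the ARC is a single
  circular harmonic, so a broad lengthscale is appropriate);
* temporal: `static` (≡ 1), `forgetting` (1−ε)^{|Δt|/2}, `periodic`
  exp(−2 sin²(π|Δt|/T_t)/l_{t,p}²) with T_t = 100 steps (one emulated day)
  and l_{t,p} = 1.0, or their product.

The Gram matrix is factorized by Cholesky with σ_n² = 10⁻² observation
noise on the diagonal and adaptive jitter (10⁻¹⁰ doubling to 10⁻⁶; failure
raises a conditioning error). A sliding window (default 500 most recent
samples) bounds the O(n³) cost of long runs; `window=None` gives exact
inference. Posterior variances within 10⁻¹⁰ of zero are clamped.

**Target normalization.** The kernels have unit variance while Δρ
observations have magnitude ~0.1, so on the raw scale the acquisition's
κσ term structurally dominates μ whenever the temporal kernel regrows
variance, and the controller explores forever. The controller therefore
standardizes training targets before fitting (mean/std of the windowed
history), exactly as scikit-learn's `GaussianProcessRegressor(normalize_y=True)`
does, and un-scales predictions. The bare estimator defaults to
`normalize_y=False`, matching the textbook zero-mean equations; the
closed-loop path enables it.

**Forgetting conventions.** Two printed conventions coexist and are kept
separate deliberately: the forgetting kernel decays as (1−ε)^{|Δt|/2}
(≈ e^{−εΔt/2} for small ε), while the half-life utilities use
ε = ln2/t_{1/2} and weight 2^{−lag/t_{1/2}} (= e^{−ε·lag}), which differ by
a factor of two in effective decay rate. `half_life_to_epsilon` /
`half_life_weight` implement the half-life convention verbatim;
`temporal_kernel` implements the kernel verbatim; neither is silently
reconciled to the other.

## Acquisition and controllers

GP-LCB: α(x) = μ(x) − κσ(x), minimized over a uniform 360-point phase grid
(1° resolution, far finer than needed in a 1-D periodic space). κ = 1 by
default on the normalized scale — exploit-leaning, with exploration driven
by variance regrowth. Exact acquisition ties break to the smallest phase.
Runs open with 12 equally spaced burn-in samples (−π + 2πk/12, occupying
step indices 0–11 and aging like any other sample).

Controllers: `tv` (spatio-temporal kernel; the kernel kind defaults to the
one matched to the configured drift — forgetting for gradual, periodic for
periodic, their product for superimposed), `static` (time-invariant
BayesOpt; identical to `tv` with ε = 0 and no periodic factor, which is
tested as an exact equality), and `scheduler`, a non-learning baseline that
replays the optimum trajectory of the *anticipated* period cyclically —
the natural clinical comparator for period-mismatch experiments.

## Drift scenarios and regret

The PRC offset Δθ_k follows: a linear ramp 0 → −A over the run (gradual), a
raised cosine 0 → −A → 0 per period (periodic, default 100 steps/cycle,
A = π), their sum (superimposed), optionally with seeded Gaussian jitter
(robustness scenarios use std 0.75 and 1.5 rad). Because the offset
translates the ARC, the true optimum is ψ*_k = wrap(ψ*₀ − Δθ_k) with
ψ*₀ = −π; this translation rule is validated against brute-force ARC
rescans at eight offsets.

Regret is accounted on the suppression scale (f = −Δρ, so more suppression
is better): R_k = f(ψ*_k) − f(ψ_target_k) ≥ 0 up to measurement noise.
`metrics.regret` computes exactly this difference for whatever values are
passed; the cumulative regret is the running *mean* (the undivided running
sum is exposed alongside), and a run is summarized by the trapezoidal AUC
of the cumulative-regret curve in step units. f(ψ*_k) is approximated by
the baseline-optimum response f₀(ψ*₀), measured once per run on a copy of
the burned-in state — valid because the offset translates the ARC without
reshaping it. The analytic toy objective (−A·cos(x − ψ*_k) + noise) returns
the exact −A instead and is used for fast controller tests.

## Problem sizes used in tests

The test suite runs the closed loop at reduced scale: 300 optimization
steps (three 100-step drift cycles) with a 24 s trial protocol — 14 s
resettle, 6 s baseline, 4 s stimulation. The 24 s floor comes from the
measured recovery time of the population after a desynchronizing trial
(~15 s for susceptible seeds): shorter steps leave the next baseline
contaminated by the previous trial and the trial-to-trial scores stop
being comparable. Sensitivity sweeps use three paired seeds per grid
point; controller comparisons use five. Full-scale 3000-step runs with the
58 s protocol use the same code paths and configs.

## What the testbed does and does not show

The synthetic population reproduces the features the controller is built
for — a smooth single-harmonic periodic objective, slow gradual/periodic
drift of its optimum, and trial-level measurement noise from finite
averaging windows. It does not emulate measurement artifacts, abrupt regime
switches, multi-dimensional parameter spaces, stimulation side effects, or
biophysical detail (conduction delays, field spread, spiking dynamics), so
passing tests demonstrate correct controller behaviour under the modelled
drift classes, not clinical performance.

## Known limitations

* Kernel hyperparameters are fixed per run (no marginal-likelihood
  optimization); the ε and period-offset sweeps are the provided selection
  tools.
* Exact GP inference is cubic in the window length.
* The scheduler baseline assumes the anticipated cycle's optimum
  trajectory is known; it quantifies mis-anticipation, not schedule
  learning.
* Near the ARC zero crossings (±π/2) the objective is below the noise
  floor, so any method's behaviour there is sign-indeterminate.
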