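# tvbopt — time-varying Bayesian optimization for phase-locked neurostimulation

Closed-loop neurostimulation therapies (deep brain stimulation for
Parkinson's disease or Essential Tremor, and related oscillopathies) must
pick stimulation settings that suppress a pathologically synchronous neural
biomarker. The best setting is not fixed: it drifts gradually with disease
progression and cycles with circadian or medication rhythms. `tvbopt`
implements a **time-varying Bayesian optimization (TV-BayesOpt)** controller
that tracks a drifting optimal stimulation phase, together with the coupled
Kuramoto oscillator testbed used to evaluate it.

## The model and the algorithm

**Testbed.** N = 50 phase oscillators θᵢ with natural frequencies drawn
around f₀ = 8 Hz evolve under global coupling and phase-locked stimulation:

    dθᵢ/dt = ωᵢ + (γ/N) Σⱼ sin(θⱼ − θᵢ) + I·X(t)·Z(θᵢ),   Z(θ) = −sin(θ + Δθ)

The population order parameter ρ·e^{iψ} = ⟨e^{iθ}⟩ summarizes synchrony
(ρ ≈ 0.8 at the unstimulated steady state). Stimulation pulses X(t) are
phase-locked to a target mean phase ψ_target; each optimization step scores
one trial by the normalized coherence change

    y = Δρ = (ρ̄_stim − ρ̄_baseline) / ρ̄_baseline .

Δρ as a function of ψ_target is the amplitude response curve (ARC) — the
objective being minimized (its minimum sits at ψ* = −π for Δθ = 0, and an
offset Δθ added to the PRC translates it to ψ* = −π − Δθ).

**Controller.** A Gaussian-process surrogate over (phase, step index) with a
spatio-temporal covariance — the Hadamard product of a periodic spatial
kernel exp(−2 sin²(π|x−x′|/T_x)/l_x²) with a temporal kernel that is either
constant (time-invariant BayesOpt), a *forgetting* kernel (1−ε)^{|t−t′|/2},
a *periodic* kernel exp(−2 sin²(π|t−t′|/T_t)/l_{t,p}²), or their product.
The next phase minimizes the lower confidence bound α(x) = μ(x) − κσ(x) on a
360-point phase grid. Performance is scored by regret against the true
drifting optimum and summarized by the area under the cumulative
(running-mean) regret curve — lower AUC means better tracking.

## Worked example

Scan the baseline ARC, then track a 50-step periodic drift with the
time-varying and the time-invariant controller (24 s trials, identical
seeds):

```bash
tvbopt simulate --config examples/periodic.json --grid 12 --seed 0 --out arc.csv
# ARC minimum: psi*=-3.141593 rad, delta_rho=-0.139049

tvbopt optimize --config examples/periodic.json --out run_tv.csv
# final cumulative regret +0.037087, AUC +7.238

tvbopt optimize --config examples/periodic.json --mode static --out run_static.csv
# final cumulative regret +0.060435, AUC +10.210
```

The scan finds the desynchronizing optimum at antiphase (Δρ = −0.14, a 14 %
coherence drop). Over 150 optimization steps the time-varying controller
(periodic temporal kernel, T_t = 50) accumulates ~30 % less regret than
static BayesOpt (AUC 7.2 vs 10.2) because it re-weights samples taken at the
same point of the drift cycle. Each run writes a CSV trace (one row per
step: tested phase, true optimum, Δρ, regret, cumulative regret) plus a
sidecar JSON that replays the run byte-for-byte.

The library mirrors the CLI: `TimeVaryingGPRegressor` is a scikit-learn
style estimator (`fit`/`predict(return_std=True)`, `get_params`, `clone`),
and `run_bayesopt`, `run_scheduler`, `arc_scan`, `make_drift`,
`sweep_epsilon`, `sweep_period_offset` compose the same experiments in
Python.

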