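"""Coupled Kuramoto oscillator population under phase-locked stimulation.

The population models a synchronous disease biomarker (e.g. tremor-band
activity): N phase oscillators with Gaussian-distributed natural frequencies
about ``f0`` and global sinusoidal coupling ``gamma``.  Exogenous stimulation
of intensity ``I`` perturbs every oscillator through a type-II phase response
curve Z(theta) = -sin(theta + offset), gated by a pulse train X(t) that is
phase-locked to the population mean phase.

The closed-loop objective is the normalized change in mean phase-coherence

    delta_rho = (rho_stim_mean - rho_baseline_mean) / rho_baseline_mean

produced by stimulating at a target mean phase; its dependence on the target
phase is the amplitude response curve (ARC) that the optimizer explores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._sim import simulate_window

__all__ = [
    "KuramotoParams",
    "PopulationState",
    "PRCSpec",
    "StimProtocol",
    "OrderParameter",
    "TrialResult",
    "wrap_angle",
    "init_population",
    "order_parameter",
    "step_population",
    "burn_in",
    "run_stimulation_trial",
    "arc_scan",
]

_NO_STIM = 10**15  # stim start index far beyond any window


def wrap_angle(theta):
    """Wrap angles to (-pi, pi]."""
    w = np.mod(np.asarray(theta) + np.pi, 2.0 * np.pi) - np.pi
    w = np.where(w == -np.pi, np.pi, w)
    return w if w.ndim else float(w)


@dataclass(frozen=True)
class KuramotoParams:
    """Population parameters.

    ``sigma_rel`` is the oscillator frequency spread as a fraction of ``f0``
    (``sigma_mode="relative"``, the default) or in Hz (``"absolute"``).
    ``freq_clip`` redraws frequencies falling more than this many Hz from
    ``f0``; ``None`` disables clipping.
    """

    n_oscillators: int = 50
    f0: float = 8.0
    sigma_rel: float = 0.0075
    gamma: float = 0.8
    intensity: float = 30.0
    dt: float = 1e-3
    freq_clip: float | None = 0.15
    sigma_mode: str = "relative"

    def __post_init__(self):
        if self.n_oscillators < 1:
            raise ValueError("n_oscillators must be >= 1")
        if self.f0 <= 0:
            raise ValueError("f0 must be > 0")
        if self.sigma_rel < 0:
            raise ValueError("sigma_rel must be >= 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.sigma_mode not in ("relative", "absolute"):
            raise ValueError(f"unknown sigma_mode: {self.sigma_mode!r}")

    @property
    def sigma_hz(self) -> float:
        return self.sigma_rel * self.f0 if self.sigma_mode == "relative" else self.sigma_rel


@dataclass
class PopulationState:
    """Oscillator phases (wrapped to (-pi, pi]) and fixed angular frequencies."""

    phases: np.ndarray
    omegas: np.ndarray
    time_s: float = 0.0

    def copy(self) -> "PopulationState":
        return PopulationState(self.phases.copy(), self.omegas.copy(), self.time_s)


@dataclass(frozen=True)
class PRCSpec:
    """Type-II phase response curve Z(theta) = -sin(theta + offset)."""

    offset: float = 0.0

    def response(self, theta):
        return -np.sin(np.asarray(theta) + self.offset)


@dataclass(frozen=True)
class StimProtocol:
    """Timing of one optimization step.

    Each step simulates ``step_duration_s`` seconds; stimulation is applied
    only during the trailing ``stim_window_s``, and the baseline coherence is
    averaged over the ``baseline_window_s`` immediately before stimulation.
    ``refractory`` is the minimum fraction of a mean period between pulses.
    """

    step_duration_s: float = 58.0
    stim_window_s: float = 8.0
    baseline_window_s: float = 25.0
    pulse_width_s: float = 1e-3
    refractory: float = 0.5

    def __post_init__(self):
        if self.stim_window_s + self.baseline_window_s > self.step_duration_s:
            raise ValueError("stim_window_s + baseline_window_s must be <= step_duration_s")
        if self.pulse_width_s <= 0:
            raise ValueError("pulse_width_s must be > 0")


@dataclass(frozen=True)
class OrderParameter:
    rho: float
    psi: float


@dataclass(frozen=True)
class TrialResult:
    rho_baseline: float
    rho_stim: float
    delta_rho: float


def init_population(params: KuramotoParams, seed: int) -> PopulationState:
    """Draw initial phases uniform on [0, 2pi) and Gaussian frequencies.

    Frequencies falling outside ``f0 +/- freq_clip`` Hz are redrawn rather
    than clamped, so no probability mass accumulates at the boundary.
    """
    rng = np.random.default_rng(seed)
    n = params.n_oscillators
    freqs = rng.normal(params.f0, params.sigma_hz, size=n)
    if params.freq_clip is not None and params.sigma_hz > 0:
        bad = np.abs(freqs - params.f0) > params.freq_clip
        while np.any(bad):
            freqs[bad] = rng.normal(params.f0, params.sigma_hz, size=int(bad.sum()))
            bad = np.abs(freqs - params.f0) > params.freq_clip
    phases = wrap_angle(rng.uniform(0.0, 2.0 * np.pi, size=n))
    return PopulationState(np.asarray(phases, dtype=float), 2.0 * np.pi * freqs, 0.0)


def order_parameter(state: PopulationState) -> OrderParameter:
    """Population order parameters: rho*exp(i*psi) = mean of exp(i*theta_j)."""
    if len(state.phases) == 0:
        raise ValueError("cannot compute order parameter of an empty population")
    z = np.exp(1j * state.phases).mean()
    return OrderParameter(float(np.abs(z)), float(wrap_angle(np.angle(z))))


def step_population(
    state: PopulationState,
    params: KuramotoParams,
    prc: PRCSpec,
    stim_active: bool = False,
    form: str = "meanfield",
    wrap: bool = True,
) -> PopulationState:
    """One explicit Euler step of the population dynamics.

    ``form="pairwise"`` evaluates the full O(N^2) coupling sum
    (gamma/N) * sum_j sin(theta_j - theta_i); ``form="meanfield"`` uses the
    identical O(N) order-parameter form gamma*rho*sin(psi - theta_i).  The two
    drifts are algebraically equal, so both integrate the same dynamics.
    """
    theta = state.phases
    if form == "pairwise":
        coupling = params.gamma * np.mean(np.sin(theta[None, :] - theta[:, None]), axis=1)
    elif form == "meanfield":
        op = order_parameter(state)
        coupling = params.gamma * op.rho * np.sin(op.psi - theta)
    else:
        raise ValueError(f"unknown form: {form!r}")
    dtheta = state.omegas + coupling
    if stim_active:
        dtheta = dtheta + params.intensity * prc.response(theta)
    new = theta + params.dt * dtheta
    if wrap:
        new = wrap_angle(new)
    return PopulationState(new, state.omegas, state.time_s + params.dt)


def burn_in(state: PopulationState, params: KuramotoParams, duration_s: float) -> PopulationState:
    """Integrate without stimulation for ``duration_s`` seconds (in place on a copy)."""
    out = state.copy()
    n_steps = int(round(duration_s / params.dt))
    simulate_window(
        out.phases, out.omegas, params.gamma, 0.0, 0.0, params.dt,
        n_steps, _NO_STIM, 0.0, 1, 1, params.f0,
    )
    out.time_s += n_steps * params.dt
    return out


def rho_trace(state: PopulationState, params: KuramotoParams, duration_s: float):
    """Unstimulated rho time series over ``duration_s``; advances the state copy.

    Returns ``(rho, new_state)`` with one rho sample per integration step.
    """
    out = state.copy()
    n_steps = int(round(duration_s / params.dt))
    rho = simulate_window(
        out.phases, out.omegas, params.gamma, 0.0, 0.0, params.dt,
        n_steps, _NO_STIM, 0.0, 1, 1, params.f0,
    )
    out.time_s += n_steps * params.dt
    return rho, out


def run_stimulation_trial(
    state: PopulationState,
    params: KuramotoParams,
    prc: PRCSpec,
    protocol: StimProtocol,
    psi_target: float,
) -> tuple[TrialResult, PopulationState]:
    """Simulate one optimization step and score it with delta_rho.

    The first ``step_duration_s - stim_window_s`` seconds run unstimulated
    (letting the population re-settle after the previous step); baseline
    coherence is averaged over the ``baseline_window_s`` immediately before
    stimulation, and pulses phase-locked to ``psi_target`` are delivered
    during the trailing ``stim_window_s``.  Returns the trial result and the
    evolved state, which the caller carries into the next step.
    """
    dt = params.dt
    n_steps = int(round(protocol.step_duration_s / dt))
    stim_start = n_steps - int(round(protocol.stim_window_s / dt))
    base_start = stim_start - int(round(protocol.baseline_window_s / dt))
    pulse_steps = max(1, int(round(protocol.pulse_width_s / dt)))
    refr_steps = max(1, int(round(protocol.refractory / (params.f0 * dt))))

    out = state.copy()
    rho = simulate_window(
        out.phases, out.omegas, params.gamma, params.intensity, prc.offset,
        dt, n_steps, stim_start, float(psi_target), pulse_steps, refr_steps, params.f0,
    )
    out.time_s += n_steps * dt
    rho_base = float(rho[base_start:stim_start].mean())
    rho_stim = float(rho[stim_start:].mean())
    if rho_base <= 0.0:
        raise ValueError("degenerate baseline: mean phase-coherence is zero")
    return TrialResult(rho_base, rho_stim, (rho_stim - rho_base) / rho_base), out


def arc_scan(
    params: KuramotoParams,
    prc: PRCSpec,
    protocol: StimProtocol,
    phase_grid,
    seed: int,
    burn_in_s: float = 200.0,
    state: PopulationState | None = None,
):
    """Empirical amplitude response curve: one trial per grid phase.

    All trials start from the same burned-in state (or the supplied
    ``state``), so differences across phases reflect the stimulation phase
    alone.  Returns an array of (phase, delta_rho) rows.
    """
    phase_grid = np.atleast_1d(np.asarray(phase_grid, dtype=float))
    if phase_grid.size == 0:
        raise ValueError("phase_grid must be non-empty")
    if state is None:
        state = burn_in(init_population(params, seed), params, burn_in_s)
    rows = np.empty((phase_grid.size, 2))
    for i, target in enumerate(phase_grid):
        result, _ = run_stimulation_trial(state.copy(), params, prc, protocol, target)
        rows[i] = (target, result.delta_rho)
    return rows
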