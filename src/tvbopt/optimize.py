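"""GP-LCB acquisition and the closed-loop optimization controllers.

``run_bayesopt`` implements both the time-varying controller (spatio-temporal
kernel ages samples by their optimization-step index) and, with
``kernel_kind="static"``, standard time-invariant Bayesian optimization.
Each step refits the surrogate on the sample history, evaluates the lower
confidence bound alpha = mu - kappa*sigma on a uniform candidate phase grid
at the current step index, tests the minimizing phase, and logs regret
against the known drifting optimum.  ``run_scheduler`` is the non-learning
baseline that replays a fixed per-time-of-cycle phase schedule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gp import GPHyperparams, PosteriorEstimate, TimeVaryingGPRegressor, VAR_TOL
from .kuramoto import wrap_angle

__all__ = [
    "AcquisitionSpec",
    "OptimizationTrace",
    "lcb",
    "select_next",
    "burn_in_schedule",
    "candidate_grid",
    "run_bayesopt",
    "run_scheduler",
]


@dataclass(frozen=True)
class AcquisitionSpec:
    """LCB exploration weight and candidate-grid resolution."""

    kappa: float = 1.0
    grid_size: int = 360
    tie_break: str = "smallest_phase"

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")
        if self.tie_break != "smallest_phase":
            raise ValueError(f"unknown tie_break rule: {self.tie_break!r}")


@dataclass
class OptimizationTrace:
    """Per-step record of one closed-loop run (the unit of all metrics)."""

    step: np.ndarray
    delta_theta: np.ndarray
    psi_true: np.ndarray
    psi_target: np.ndarray
    y: np.ndarray
    f_at_true: np.ndarray
    regret: np.ndarray
    mode: str = ""
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.step)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": self.step,
                "delta_theta": self.delta_theta,
                "psi_true": self.psi_true,
                "psi_target": self.psi_target,
                "delta_rho": self.y,
                "f_at_true": self.f_at_true,
                "regret": self.regret,
            }
        )


def lcb(post: PosteriorEstimate, spec: AcquisitionSpec) -> np.ndarray:
    """Lower confidence bound alpha = mu - kappa * sigma, elementwise."""
    if np.any(post.var < -VAR_TOL):
        raise FloatingPointError("negative posterior variance beyond tolerance")
    return post.mu - spec.kappa * np.sqrt(np.maximum(post.var, 0.0))


def select_next(acq, grid, spec: AcquisitionSpec | None = None) -> float:
    """Grid phase minimizing the acquisition; exact ties -> smallest phase."""
    acq = np.asarray(acq, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("candidate grid must be non-empty")
    if acq.shape != grid.shape:
        raise ValueError("acq and grid must have the same length")
    ties = np.flatnonzero(acq == acq.min())
    return float(grid[ties[np.argmin(grid[ties])]])


def burn_in_schedule(n_init: int) -> np.ndarray:
    """n_init equally spaced phases on the circle: -pi + 2*pi*k/n_init."""
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    return -np.pi + 2.0 * np.pi * np.arange(n_init) / n_init


def candidate_grid(grid_size: int) -> np.ndarray:
    """Uniform acquisition grid on [-pi, pi)."""
    return -np.pi + 2.0 * np.pi * np.arange(grid_size) / grid_size


def _objective_truth(objective, k):
    psi_true = objective.true_optimum(k) if hasattr(objective, "true_optimum") else np.nan
    f_true = objective.true_value(k) if hasattr(objective, "true_value") else np.nan
    dth = objective.delta_theta(k) if hasattr(objective, "delta_theta") else 0.0
    return psi_true, f_true, dth


def _make_trace(n_steps, mode, seed):
    z = np.zeros(n_steps)
    return OptimizationTrace(
        step=np.arange(n_steps), delta_theta=z.copy(), psi_true=z.copy(),
        psi_target=z.copy(), y=z.copy(), f_at_true=z.copy(), regret=z.copy(),
        mode=mode, seed=seed,
    )


def _log_step(trace, objective, k, psi):
    psi = float(wrap_angle(psi))
    y = float(objective(psi, k))
    psi_true, f_true, dth = _objective_truth(objective, k)
    trace.delta_theta[k] = dth
    trace.psi_true[k] = psi_true
    trace.psi_target[k] = psi
    trace.y[k] = y
    trace.f_at_true[k] = f_true
    # regret on the suppression scale: tested outcome minus the optimum's
    # outcome (>= 0 up to measurement noise); see metrics.regret
    trace.regret[k] = y - f_true


def run_bayesopt(
    objective,
    hp: GPHyperparams,
    spec: AcquisitionSpec | None = None,
    n_steps: int = 3000,
    n_init: int = 12,
    seed: int = 0,
) -> OptimizationTrace:
    """Closed-loop (TV-)BayesOpt: burn-in schedule, then the GP-LCB loop.

    ``objective`` maps ``(psi_target, step_index) -> observed delta_rho`` and
    may expose ``true_optimum(k)`` / ``true_value(k)`` / ``delta_theta(k)``
    for regret logging.  All randomness lives in the objective; the loop
    itself is deterministic, so identical configuration and seed reproduce
    the trace exactly.
    """
    spec = spec or AcquisitionSpec()
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    mode = "static" if hp.kernel_kind == "static" else "tv"
    trace = _make_trace(n_steps, mode, seed)
    grid = candidate_grid(spec.grid_size)
    grid_t = np.empty_like(grid)
    gpr = TimeVaryingGPRegressor(
        kernel_kind=hp.kernel_kind, l_x=hp.l_x, T_x=hp.T_x, epsilon=hp.epsilon,
        T_t=hp.T_t, l_tp=hp.l_tp, sigma_n2=hp.sigma_n2, window=hp.window,
        normalize_y=getattr(hp, "normalize_y", True),
    )
    xs: list[float] = []
    ts: list[float] = []
    ys: list[float] = []

    schedule = burn_in_schedule(min(n_init, n_steps))
    for k in range(n_steps):
        if k < len(schedule):
            psi = schedule[k]
        else:
            gpr.fit(np.column_stack([xs, ts]), np.asarray(ys))
            grid_t.fill(k)
            mu, std = gpr.predict(np.column_stack([grid, grid_t]), return_std=True)
            acq = lcb(PosteriorEstimate(mu, std**2), spec)
            psi = select_next(acq, grid, spec)
        try:
            _log_step(trace, objective, k, psi)
        except (FloatingPointError, np.linalg.LinAlgError, ValueError) as err:
            raise type(err)(f"step {k}: {err}") from err
        xs.append(trace.psi_target[k])
        ts.append(float(k))
        ys.append(trace.y[k])
    return trace


def run_scheduler(objective, daily_schedule, n_steps: int) -> OptimizationTrace:
    """Non-learning baseline: replay ``daily_schedule`` cyclically.

    ``daily_schedule`` is a sequence of phases covering one anticipated
    period (or a mapping from time-of-cycle index to phase); step k applies
    entry ``k mod period``.
    """
    if hasattr(daily_schedule, "keys"):
        keys = sorted(daily_schedule)
        sched = np.array([daily_schedule[i] for i in keys], dtype=float)
    else:
        sched = np.asarray(daily_schedule, dtype=float)
    if sched.size == 0:
        raise ValueError("daily_schedule must cover at least one step")
    trace = _make_trace(n_steps, "scheduler", None)
    for k in range(n_steps):
        _log_step(trace, objective, k, sched[k % sched.size])
    return trace
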