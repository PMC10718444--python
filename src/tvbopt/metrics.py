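"""Regret bookkeeping and the two sensitivity sweeps.

Regret is measured on the suppression scale: at step k the controller's
shortfall is f(psi*_k) - f(psi_target_k) where f is the suppression achieved
(the negated delta_rho, so larger is better).  The cumulative regret is the
running mean of per-step regrets, and a whole run is summarized by the area
under its cumulative-regret curve (trapezoidal, step units) — lower AUC means
better tracking.

The sweeps rerun complete closed-loop experiments over a grid of forgetting
factors (forgetting vs forgetting-periodic kernels, superimposed drift) or of
drift-period offsets (scheduler vs periodic vs forgetting-periodic, periodic
drift), with common seeds across controllers at each grid point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RegretSeries",
    "regret",
    "cumulative_regret",
    "trace_series",
    "sweep_epsilon",
    "sweep_period_offset",
]


@dataclass(frozen=True)
class RegretSeries:
    regret: np.ndarray
    cum_regret: np.ndarray  # running mean, CR_k = mean(regret[0..k])
    cum_sum: np.ndarray     # undivided running sum
    auc: float              # trapezoid over step index of cum_regret


def regret(f_true, f_tested):
    """Per-step regret as printed: R = f(psi*_k) - f(psi_target_k).

    Callers pass objective values on the suppression scale (higher = more
    symptom suppression), which makes R >= 0 up to measurement noise.
    """
    out = np.asarray(f_true, dtype=float) - np.asarray(f_tested, dtype=float)
    return out if out.ndim else float(out)


def cumulative_regret(regrets) -> RegretSeries:
    """Running-mean cumulative regret and its trapezoidal AUC."""
    r = np.atleast_1d(np.asarray(regrets, dtype=float))
    if r.size == 0:
        raise ValueError("regrets must be non-empty")
    cs = np.cumsum(r)
    cr = cs / np.arange(1, r.size + 1)
    auc = float(np.trapezoid(cr)) if r.size > 1 else 0.0
    return RegretSeries(r, cr, cs, auc)


def trace_series(trace) -> RegretSeries:
    """Regret series of an :class:`~tvbopt.optimize.OptimizationTrace`."""
    return cumulative_regret(trace.regret)


def _auc_of_run(cfg):
    from .engine import run_from_config  # deferred: engine builds on metrics' consumers

    return trace_series(run_from_config(cfg)).auc


def sweep_epsilon(config, epsilon_grid, kernel_kinds=("forgetting", "forgetting_periodic"),
                  seeds=None) -> pd.DataFrame:
    """Forgetting-factor sensitivity on the configured (superimposed) scenario.

    One full optimization run per (epsilon, kernel kind, seed), with seeds
    shared across kernel kinds so comparisons at a grid point are paired.
    Returns a tidy table with columns (sweep_value, mode, auc, n_steps, seed).
    """
    from .config import RunConfig  # local: avoid import cycle at module load

    cfg = config if isinstance(config, RunConfig) else RunConfig.model_validate(config)
    seeds = [cfg.seed] if seeds is None else list(seeds)
    rows = []
    for eps in epsilon_grid:
        for kind in kernel_kinds:
            for seed in seeds:
                run_cfg = cfg.model_copy(deep=True)
                run_cfg.mode = "tv"
                run_cfg.seed = int(seed)
                run_cfg.gp.epsilon = float(eps)
                run_cfg.gp.kernel_kind = kind
                rows.append(
                    {"sweep_value": float(eps), "mode": kind,
                     "auc": _auc_of_run(run_cfg), "n_steps": cfg.n_steps,
                     "seed": int(seed)}
                )
    return pd.DataFrame(rows)


def sweep_period_offset(config, offset_grid, seeds=None) -> pd.DataFrame:
    """Drift-period mismatch sensitivity on the configured periodic scenario.

    The anticipated period (the temporal-kernel period T_t and the
    scheduler's cycle length) stays fixed at ``config.gp.T_t`` while the true
    drift period is ``T_t + offset`` for each grid offset.  Three controllers
    run per offset with paired seeds: the scheduler, TV-BayesOpt with the
    periodic kernel, and TV-BayesOpt with the forgetting-periodic kernel.
    """
    from .config import RunConfig

    cfg = config if isinstance(config, RunConfig) else RunConfig.model_validate(config)
    seeds = [cfg.seed] if seeds is None else list(seeds)
    rows = []
    for offset in offset_grid:
        true_period = int(round(cfg.gp.T_t + offset))
        if true_period < 1:
            raise ValueError("offset makes the true drift period < 1 step")
        for mode, kind in (("scheduler", None), ("tv", "periodic"),
                           ("tv", "forgetting_periodic")):
            for seed in seeds:
                run_cfg = cfg.model_copy(deep=True)
                run_cfg.mode = mode
                run_cfg.seed = int(seed)
                run_cfg.scenario.period_steps = true_period
                if kind is not None:
                    run_cfg.gp.kernel_kind = kind
                rows.append(
                    {"sweep_value": float(offset),
                     "mode": mode if kind is None else kind,
                     "auc": _auc_of_run(run_cfg), "n_steps": cfg.n_steps,
                     "seed": int(seed)}
                )
    return pd.DataFrame(rows)
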