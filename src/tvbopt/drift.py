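"""Drift schedules for the optimal stimulation phase, and trial objectives.

Nonstationarity is injected by adding a time-varying offset ``delta_theta_k``
to the population PRC, Z(theta) = -sin(theta + delta_theta_k).  Because the
offset translates the amplitude response curve without reshaping it, the true
optimal stimulation phase moves as psi*_k = wrap(psi*_0 - delta_theta_k),
where psi*_0 = -pi is the empirically identified baseline optimum.

Schedules:

* ``gradual``       linear ramp 0 -> -amplitude over the run (disease
                    progression at the slow timescale)
* ``periodic``      raised-cosine 0 -> -amplitude -> 0 every ``period_steps``
                    (circadian / medication cycles; 100 steps ~ 1 day)
* ``superimposed``  sum of the two
* ``none``          stationary objective

``noise_std`` adds seeded Gaussian jitter to the offset trajectory, used for
robustness scenarios.

Two trial objectives expose the common interface ``obj(psi_target, k)`` plus
``true_optimum(k)``, ``true_value(k)`` and ``delta_theta(k)``:
:class:`ToyObjective` is an analytic stand-in (cosine valley tracking the
drifting optimum) for fast controller tests; :class:`KuramotoObjective` runs
a full stimulation trial per call, carrying the population state across
optimization steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kuramoto as km
from .kuramoto import wrap_angle

__all__ = [
    "DriftSchedule",
    "make_drift",
    "true_optimum",
    "toy_objective",
    "ToyObjective",
    "KuramotoObjective",
    "PSI_STAR_BASELINE",
]

DRIFT_KINDS = ("none", "gradual", "periodic", "superimposed")

PSI_STAR_BASELINE = -np.pi  # baseline ARC minimum with delta_theta = 0


@dataclass(frozen=True)
class DriftSchedule:
    kind: str
    n_steps: int
    period_steps: int
    amplitude: float
    noise_std: float
    seed: int
    offsets: np.ndarray  # delta_theta_k, length n_steps


def _ramp(n_steps: int, amplitude: float) -> np.ndarray:
    if n_steps == 1:
        return np.zeros(1)
    return -amplitude * np.arange(n_steps) / (n_steps - 1)


def _cycle(n_steps: int, period_steps: int, amplitude: float) -> np.ndarray:
    k = np.arange(n_steps)
    return -0.5 * amplitude * (1.0 - np.cos(2.0 * np.pi * k / period_steps))


def make_drift(
    kind: str = "gradual",
    n_steps: int = 3000,
    period_steps: int = 100,
    amplitude: float = np.pi,
    noise_std: float = 0.0,
    seed: int = 0,
) -> DriftSchedule:
    """Build the PRC-offset schedule delta_theta_k for one run.

    The gradual ramp ends exactly at ``-amplitude`` on the last step; the
    periodic component returns to 0 every ``period_steps`` with its minimum
    ``-amplitude`` mid-cycle.
    """
    if kind not in DRIFT_KINDS:
        raise ValueError(f"unknown drift kind: {kind!r} (expected one of {DRIFT_KINDS})")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if period_steps < 1:
        raise ValueError("period_steps must be >= 1")
    if kind == "none":
        offsets = np.zeros(n_steps)
    elif kind == "gradual":
        offsets = _ramp(n_steps, amplitude)
    elif kind == "periodic":
        offsets = _cycle(n_steps, period_steps, amplitude)
    else:
        offsets = _ramp(n_steps, amplitude) + _cycle(n_steps, period_steps, amplitude)
    if noise_std > 0:
        offsets = offsets + np.random.default_rng(seed).normal(0.0, noise_std, n_steps)
    return DriftSchedule(kind, n_steps, period_steps, float(amplitude),
                         float(noise_std), int(seed), offsets)


def true_optimum(prc_offset: float, psi_star0: float = PSI_STAR_BASELINE) -> float:
    """Location of the ARC minimum under a PRC offset: wrap(psi*_0 - offset)."""
    return float(wrap_angle(psi_star0 - prc_offset))


def toy_objective(x, k, drift: DriftSchedule, amplitude: float = 1.0,
                  noise_std_y: float = 0.0, rng=None) -> float:
    """Analytic ARC stand-in: y = -amplitude * cos(x - psi*_k) + noise.

    The global minimum ``-amplitude`` sits at the drifting optimum psi*_k,
    mirroring the shape of the measured ARC (most negative delta_rho at the
    optimum, most positive half a cycle away).
    """
    psi_star = true_optimum(drift.offsets[k])
    y = -amplitude * np.cos(np.asarray(x, dtype=float) - psi_star)
    if noise_std_y > 0:
        rng = np.random.default_rng(None) if rng is None else rng
        y = y + rng.normal(0.0, noise_std_y, size=np.shape(y))
    return float(y) if np.ndim(y) == 0 else y


class ToyObjective:
    """Stateful wrapper around :func:`toy_objective` with seeded noise."""

    def __init__(self, drift: DriftSchedule, amplitude: float = 1.0,
                 noise_std_y: float = 0.0, seed: int = 0):
        self.drift = drift
        self.amplitude = float(amplitude)
        self.noise_std_y = float(noise_std_y)
        self._rng = np.random.default_rng(seed)

    def __call__(self, psi_target: float, k: int) -> float:
        return toy_objective(psi_target, k, self.drift, self.amplitude,
                             self.noise_std_y, self._rng)

    def delta_theta(self, k: int) -> float:
        return float(self.drift.offsets[k])

    def true_optimum(self, k: int) -> float:
        return true_optimum(self.drift.offsets[k])

    def true_value(self, k: int) -> float:
        return -self.amplitude


class KuramotoObjective:
    """Kuramoto-backed trial objective with state carried across steps.

    On construction the population is burned in for ``burn_in_s`` seconds and
    the objective value at the baseline optimum, f0(psi*_0), is measured once
    on a copy of the state (the PRC offset translates the ARC, so this value
    approximates f_k(psi*_k) at every step).  Each call then runs one
    stimulation trial with the step's PRC offset applied, advancing the
    carried state.
    """

    def __init__(
        self,
        drift: DriftSchedule,
        params: km.KuramotoParams | None = None,
        protocol: km.StimProtocol | None = None,
        seed: int = 0,
        burn_in_s: float = 200.0,
        psi_star0: float = PSI_STAR_BASELINE,
        f_ref: float | None = None,
    ):
        self.drift = drift
        self.params = params or km.KuramotoParams()
        self.protocol = protocol or km.StimProtocol()
        self.psi_star0 = float(psi_star0)
        self.state = km.burn_in(km.init_population(self.params, seed), self.params, burn_in_s)
        if f_ref is None:
            probe, _ = km.run_stimulation_trial(
                self.state.copy(), self.params, km.PRCSpec(0.0), self.protocol, self.psi_star0
            )
            f_ref = probe.delta_rho
        self.f_ref = float(f_ref)

    def __call__(self, psi_target: float, k: int) -> float:
        prc = km.PRCSpec(float(self.drift.offsets[k]))
        result, self.state = km.run_stimulation_trial(
            self.state, self.params, prc, self.protocol, psi_target
        )
        return result.delta_rho

    def delta_theta(self, k: int) -> float:
        return float(self.drift.offsets[k])

    def true_optimum(self, k: int) -> float:
        return true_optimum(self.drift.offsets[k], self.psi_star0)

    def true_value(self, k: int) -> float:
        return self.f_ref
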