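"""Numba inner loops for the Kuramoto population.

The public API lives in :mod:`tvbopt.kuramoto`; these kernels exist so that
multi-minute closed-loop experiments (thousands of seconds of simulated time
at millisecond resolution) stay fast.  The drift computed here is the
mean-field form gamma*rho*sin(psi - theta_i), which is algebraically identical
to the full pairwise coupling sum.
"""

from __future__ import annotations

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi


@njit(cache=True)
def _wrap(a):
    while a <= -np.pi:
        a += TWO_PI
    while a > np.pi:
        a -= TWO_PI
    return a


@njit(cache=True)
def simulate_window(
    phases,
    omegas,
    gamma,
    intensity,
    prc_offset,
    dt,
    n_steps,
    stim_start_step,
    psi_target,
    pulse_steps,
    refractory_steps,
    f0,
):
    """Euler-integrate the population for ``n_steps`` steps, in place.

    Stimulation pulses of ``pulse_steps`` integration steps are delivered
    while ``step >= stim_start_step`` whenever the population mean phase psi
    comes within half an integration step of the trigger point.  The trigger
    point leads ``psi_target`` by half the pulse's phase extent so the pulse
    is centred on the target phase; a refractory of ``refractory_steps``
    prevents double triggering from psi jitter.

    Returns the per-step mean phase-coherence trace rho[0..n_steps-1]
    (measured before each Euler update).
    """
    n = phases.shape[0]
    rho = np.empty(n_steps)
    pulse_left = 0
    refr_left = 0
    step_adv = TWO_PI * f0 * dt          # mean phase advance per step
    lead = 0.5 * step_adv * pulse_steps  # centre the pulse on the target
    half_step = 0.5 * step_adv
    for s in range(n_steps):
        c = 0.0
        sn = 0.0
        for i in range(n):
            c += np.cos(phases[i])
            sn += np.sin(phases[i])
        c /= n
        sn /= n
        r = np.sqrt(c * c + sn * sn)
        psi = np.arctan2(sn, c)
        rho[s] = r

        if s >= stim_start_step and refr_left == 0 and pulse_left == 0:
            d = _wrap(psi - psi_target + lead)
            if -half_step <= d < half_step:
                pulse_left = pulse_steps
                refr_left = refractory_steps
        if refr_left > 0:
            refr_left -= 1

        stim_on = pulse_left > 0
        if stim_on:
            pulse_left -= 1

        for i in range(n):
            dtheta = omegas[i] + gamma * r * np.sin(psi - phases[i])
            if stim_on:
                dtheta += intensity * (-np.sin(phases[i] + prc_offset))
            phases[i] = _wrap(phases[i] + dt * dtheta)
    return rho
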