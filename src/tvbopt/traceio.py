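"""Trace serialization: human-diffable CSV plus a sidecar JSON for replay."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .kuramoto import wrap_angle

__all__ = ["write_trace", "read_trace", "sidecar_path"]

logger = logging.getLogger("tvbopt")

COLUMNS = ["step", "sim_time_s", "delta_theta", "psi_true", "psi_target",
           "delta_rho", "regret", "cum_regret"]

ANGLE_COLUMNS = ("delta_theta", "psi_true", "psi_target")


def sidecar_path(path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".config.json")


def write_trace(trace, series, path, config=None, step_duration_s: float = 58.0,
                burn_in_s: float = 200.0) -> Path:
    """Write one run as CSV (one row per optimization step) plus sidecar JSON.

    Angles are serialized in radians wrapped to (-pi, pi] with 6 decimal
    places; ``sim_time_s`` is the simulated time at the end of each step.
    When ``config`` (a RunConfig) is given, its resolved JSON — sufficient
    for byte-exact replay — is written next to the CSV.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if config is not None:
        step_duration_s = config.protocol.step_duration_s
        burn_in_s = config.burn_in_s
    k = np.asarray(trace.step)
    df = pd.DataFrame(
        {
            "step": k,
            "sim_time_s": burn_in_s + (k + 1) * step_duration_s,
            "delta_theta": wrap_angle(trace.delta_theta),
            "psi_true": wrap_angle(trace.psi_true),
            "psi_target": wrap_angle(trace.psi_target),
            "delta_rho": trace.y,
            "regret": trace.regret,
            "cum_regret": series.cum_regret,
        }
    )
    for col in ANGLE_COLUMNS:
        df[col] = df[col].round(6)
    df.to_csv(path, index=False, float_format="%.6f")
    if config is not None:
        sidecar_path(path).write_text(config.to_json())
        logger.info("wrote %s (+ sidecar); config=%s seed=%s final CR=%.6f",
                    path, config.hash(), trace.seed, series.cum_regret[-1])
    return path


def read_trace(path) -> pd.DataFrame:
    return pd.read_csv(path)
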