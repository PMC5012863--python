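"""Strength-to-frequency mapping: the hierarchy of intrinsic timescales.

Each region's natural frequency is a decreasing function of its anatomical
node strength,

    omega_i = b - (b - a) * ((s_i - s_min) / (s_max - s_min)) ** exponent

so weakly connected (sensory-like) regions oscillate near the fast bound
``b`` and the strongest hubs near the slow bound ``a``.  The defaults
(a = 0.01 Hz, b = 0.1 Hz, exponent = 2) span the slow BOLD fluctuation
band.  The mapping depends only on the normalized rank position of each
strength, so it is invariant to rescaling the connectome.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = [
    "TimescaleParams",
    "DegenerateStrengthError",
    "assign_frequencies",
    "summarize_frequencies",
    "FrequencySummary",
    "write_frequencies",
]


class DegenerateStrengthError(ValueError):
    """All strengths equal: the frequency gradient is undefined."""


@dataclasses.dataclass(frozen=True)
class TimescaleParams:
    """Bounds and shape of the strength-to-frequency map.

    ``a`` is the slow bound in Hz (assigned to the maximum-strength node),
    ``b`` the fast bound in Hz (minimum-strength node); ``exponent``
    controls how sharply frequency falls off with strength.
    """

    a: float = 0.01
    b: float = 0.1
    exponent: float = 2.0

    def __post_init__(self):
        if not 0 < self.a < self.b:
            raise ValueError(f"require 0 < a < b, got a={self.a}, b={self.b}")
        if self.exponent <= 0:
            raise ValueError(f"exponent must be positive, got {self.exponent}")


def assign_frequencies(
    strengths: pd.Series, params: TimescaleParams = TimescaleParams()
) -> pd.Series:
    """Map node strengths to natural frequencies in Hz.

    Returns a Series aligned with ``strengths``; values lie in
    ``[params.a, params.b]`` with the endpoints attained exactly at the
    minimum- and maximum-strength nodes.
    """
    s = np.asarray(strengths, dtype=float)
    s_min, s_max = s.min(), s.max()
    if s_max <= s_min:
        raise DegenerateStrengthError(
            "all node strengths are equal; the frequency gradient is undefined"
        )
    x = (s - s_min) / (s_max - s_min)
    omega = params.b - (params.b - params.a) * x**params.exponent
    return pd.Series(omega, index=strengths.index, name="omega_hz")


@dataclasses.dataclass(frozen=True)
class FrequencySummary:
    mean_hz: float
    hub_hz: dict
    sensory_hz: dict
    hub_below_mean: bool
    sensory_above_mean: bool


def summarize_frequencies(omega: pd.Series, hub_ids, sensory_ids) -> FrequencySummary:
    """Mean frequency plus hub/sensory values and their ordering flags."""
    for rid in list(hub_ids) + list(sensory_ids):
        if rid not in omega.index:
            raise KeyError(f"unknown region id: {rid!r}")
    mean = float(omega.mean())
    hub = {r: float(omega[r]) for r in hub_ids}
    sens = {r: float(omega[r]) for r in sensory_ids}
    return FrequencySummary(
        mean_hz=mean,
        hub_hz=hub,
        sensory_hz=sens,
        hub_below_mean=all(v < mean for v in hub.values()),
        sensory_above_mean=all(v > mean for v in sens.values()),
    )


def write_frequencies(omega: pd.Series, path) -> None:
    """Write a two-column TSV (region_id, omega_hz)."""
    omega.rename_axis("region_id").to_csv(path, sep="\t")
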