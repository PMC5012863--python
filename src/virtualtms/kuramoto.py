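"""Coupled phase-oscillator dynamics on a connectome.

Integrates

    dtheta_i/dt = Omega_i + lambda * sum_j W_ji sin(theta_j - theta_i)

where ``Omega_i`` is the region's natural frequency converted to rad/s
(``Omega = 2*pi*omega`` under the default ``two-pi`` convention, so a
region oscillates at its nominal frequency in Hz; the ``literal``
convention uses the Hz value as an angular rate directly, with the
coupling recalibrated accordingly).  The BOLD-proxy observable is
``sin(theta)`` sampled at the acquisition interval after discarding the
initial transient.

The integrator is deterministic: identical weights, frequencies, config
and seed (or explicit initial phases) give identical trajectories.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "PhaseTrajectory",
    "ObservableSeries",
    "draw_initial_phases",
    "integrate_batch",
    "simulate",
    "observable",
    "order_parameter",
]


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Integration and sampling parameters.

    Parameters
    ----------
    coupling
        Global coupling strength (lambda), dimensionless, >= 0.
    dt
        Integration step in seconds.
    duration, transient
        Total simulated time and the initial span discarded before any
        observable is sampled, both in seconds.  Defaults follow 8-minute
        runs with a 2.12-minute transient.
    sampling_interval
        Observable sampling period in seconds (default 2.25 s, a typical
        fMRI repetition time).
    angular_convention
        ``"two-pi"`` converts Hz to rad/s; ``"literal"`` uses the Hz value
        as the angular rate.
    integrator
        ``"heun"`` (2nd order, default) or ``"euler"``.
    seed
        Seed for drawing uniform random initial phases when none are given.
    """

    coupling: float = 0.0028
    dt: float = 0.05
    duration: float = 480.0
    transient: float = 127.2
    sampling_interval: float = 2.25
    angular_convention: str = "two-pi"
    integrator: str = "heun"
    seed: Optional[int] = None

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not 0 <= self.transient < self.duration:
            raise ValueError(
                f"require 0 <= transient < duration, got "
                f"transient={self.transient}, duration={self.duration}"
            )
        if self.sampling_interval < self.dt:
            raise ValueError("sampling_interval must be >= dt")
        if self.coupling < 0:
            raise ValueError(f"coupling must be >= 0, got {self.coupling}")
        if self.angular_convention not in ("two-pi", "literal"):
            raise ValueError(f"unknown convention {self.angular_convention!r}")
        if self.integrator not in ("heun", "euler"):
            raise ValueError(f"unknown integrator {self.integrator!r}")

    @property
    def n_samples(self) -> int:
        return int(np.floor((self.duration - self.transient) / self.sampling_interval))

    def sample_times(self) -> np.ndarray:
        stride = max(1, round(self.sampling_interval / self.dt))
        start = round(self.transient / self.dt)
        return (start + stride * np.arange(self.n_samples)) * self.dt

    def angular_rate(self, omega_hz) -> np.ndarray:
        """Convert a frequency profile in Hz to angular rates in rad/s."""
        omega_hz = np.asarray(omega_hz, dtype=float)
        if self.angular_convention == "two-pi":
            return 2.0 * np.pi * omega_hz
        return omega_hz


@dataclasses.dataclass(frozen=True)
class PhaseTrajectory:
    """Sampled unwrapped phases: ``phases[i, t]`` in radians."""

    times: np.ndarray
    phases: np.ndarray
    region_ids: tuple

    def __post_init__(self):
        if not np.all(np.isfinite(self.phases)):
            raise FloatingPointError("non-finite phases in trajectory")


@dataclasses.dataclass(frozen=True)
class ObservableSeries:
    """BOLD-proxy signals sin(theta), one row per region."""

    times: np.ndarray
    values: np.ndarray
    region_ids: tuple

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.T, index=pd.Index(self.times, name="time_s"),
            columns=list(self.region_ids),
        )


def draw_initial_phases(n: int, seed, size: Optional[int] = None) -> np.ndarray:
    """Uniform random phases on [0, 2*pi); shape (n,) or (n, size)."""
    rng = np.random.default_rng(seed)
    shape = (n,) if size is None else (n, size)
    return rng.uniform(0.0, 2.0 * np.pi, size=shape)


def integrate_batch(
    weights: np.ndarray,
    omega_rad: np.ndarray,
    theta0: np.ndarray,
    config: SimulationConfig,
) -> np.ndarray:
    """Integrate an ensemble of independent trials in one pass.

    ``omega_rad`` and ``theta0`` have shape ``(N, B)`` (angular rates in
    rad/s may differ per trial, e.g. pre/post perturbation); returns
    sampled phases of shape ``(N, T, B)``.  Batching only amortizes the
    matrix products; each column evolves independently.
    """
    w = np.ascontiguousarray(weights, dtype=float)
    theta = np.array(theta0, dtype=float, copy=True)
    if theta.ndim != 2 or omega_rad.shape != theta.shape:
        raise ValueError(
            f"omega {omega_rad.shape} and initial phases {theta.shape} "
            f"must share shape (N, B)"
        )
    if w.shape[0] != theta.shape[0]:
        raise ValueError(
            f"{w.shape[0]}-region matrix vs {theta.shape[0]}-region phases"
        )
    lam, dt = config.coupling, config.dt
    n_steps = round(config.duration / dt)
    stride = max(1, round(config.sampling_interval / dt))
    start = round(config.transient / dt)
    n_samp = config.n_samples
    out = np.empty((theta.shape[0], n_samp, theta.shape[1]))
    heun = config.integrator == "heun"

    def drift(th):
        s, c = np.sin(th), np.cos(th)
        return omega_rad + lam * (c * (w @ s) - s * (w @ c))

    k = 0
    for step in range(n_steps + 1):
        if step >= start and (step - start) % stride == 0 and k < n_samp:
            out[:, k, :] = theta
            k += 1
        if step == n_steps:
            break
        f1 = drift(theta)
        if heun:
            f2 = drift(theta + dt * f1)
            theta += (dt / 2.0) * (f1 + f2)
        else:
            theta += dt * f1
    if not np.all(np.isfinite(out)):
        raise FloatingPointError(
            "non-finite phases during integration; reduce dt or coupling"
        )
    return out


def simulate(
    conn,
    omega: pd.Series,
    config: SimulationConfig,
    initial_phases: Optional[np.ndarray] = None,
) -> PhaseTrajectory:
    """Run one trial on a connectome and return the sampled trajectory.

    ``omega`` is the per-region natural frequency profile in Hz, aligned
    to the connectome's regions.  Initial phases default to a uniform
    random draw from ``config.seed``.
    """
    ids = list(conn.region_ids)
    if list(omega.index) != ids:
        omega = omega.reindex(ids)
        if omega.isna().any():
            missing = list(omega.index[omega.isna()])
            raise ValueError(f"frequency profile missing regions: {missing}")
    n = conn.n_regions
    if initial_phases is None:
        initial_phases = draw_initial_phases(n, config.seed)
    theta0 = np.asarray(initial_phases, dtype=float)
    if theta0.shape != (n,):
        raise ValueError(f"initial phases must have shape ({n},), got {theta0.shape}")
    omega_rad = config.angular_rate(omega.to_numpy())
    phases = integrate_batch(
        conn.weights, omega_rad[:, None], theta0[:, None], config
    )[:, :, 0]
    return PhaseTrajectory(config.sample_times(), phases, tuple(ids))


def observable(traj: PhaseTrajectory) -> ObservableSeries:
    """BOLD-proxy series sin(theta) for each region."""
    return ObservableSeries(traj.times, np.sin(traj.phases), traj.region_ids)


def order_parameter(traj: PhaseTrajectory) -> np.ndarray:
    """Kuramoto order parameter R(t) = |mean_j exp(i*theta_j(t))| in [0, 1]."""
    return np.abs(np.exp(1j * traj.phases).mean(axis=0))
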