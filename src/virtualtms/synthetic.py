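"""Synthetic study inputs: modular connectomes and band-limited signals.

The connectome generator emulates the gross features a tractography-based
whole-brain network needs for timescale-hierarchy experiments: a modular
(stochastic-block-like) topology, heavy-tailed log-normal edge weights,
one or more designated hub regions whose strength tops the distribution,
and designated sensory regions in the weak tail.  It does not attempt
anatomical fidelity to any particular parcellation.

Node-strength heterogeneity is produced by per-node gain factors drawn
from a log-normal law; an edge's weight is scaled by the geometric mean
of its endpoints' gains, hubs receive a boosted gain (and denser
attachment), and sensory nodes a damped one.  Generation is a pure
function of the spec, including its seed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .connectome import Connectome
from .kuramoto import SimulationConfig

__all__ = [
    "SYNTHETIC_COUPLING",
    "SyntheticConnectomeSpec",
    "SyntheticBoldSpec",
    "generate_connectome",
    "generate_bold",
    "generate_reference_fc",
    "default_region_ids",
]


#: global coupling for the default generated connectome (128 regions,
#: global-max normalized, two-pi angular convention), selected once by the
#: calibration procedure: it maximizes the fit to model reference FC and
#: places the network in strong partial synchrony where the designated
#: sensory and hub nodes remain imperfectly entrained.
SYNTHETIC_COUPLING = 0.07


def default_region_ids(n: int) -> tuple:
    return tuple(f"r{i:03d}" for i in range(n))


@dataclasses.dataclass(frozen=True)
class SyntheticConnectomeSpec:
    """Parameters of the synthetic connectome generator.

    ``hub_boost`` multiplies both the hub's attachment probability and its
    node gain; ``sensory_damp`` (< 1) shrinks the sensory nodes' gain and
    attachment.  ``gain_sigma`` sets the log-normal spread of per-node
    gains and hence the strength heterogeneity of the bulk.
    """

    n_regions: int = 128
    n_modules: int = 4
    hub_ids: Sequence[str] = ("r000",)
    sensory_ids: Sequence[str] = ("r096",)
    p_intra: float = 0.7
    p_inter: float = 0.35
    weight_location: float = 0.0
    weight_scale: float = 0.75
    hub_boost: float = 3.0
    sensory_damp: float = 0.4
    gain_sigma: float = 0.45
    seed: int = 0

    def __post_init__(self):
        if self.n_regions < 8:
            raise ValueError(f"need >= 8 regions, got {self.n_regions}")
        if not 1 <= self.n_modules <= self.n_regions:
            raise ValueError("n_modules must be in [1, n_regions]")
        ids = default_region_ids(self.n_regions)
        for rid in tuple(self.hub_ids) + tuple(self.sensory_ids):
            if rid not in ids:
                raise ValueError(f"designated region {rid!r} outside id range")
        if set(self.hub_ids) & set(self.sensory_ids):
            raise ValueError("hub_ids and sensory_ids must be disjoint")
        for name in ("p_intra", "p_inter"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.p_intra == 0 and self.p_inter == 0:
            raise ValueError("infeasible spec: p_intra = p_inter = 0")
        if self.hub_boost < 1:
            raise ValueError("hub_boost must be >= 1")
        if not 0 < self.sensory_damp <= 1:
            raise ValueError("sensory_damp must lie in (0, 1]")
        object.__setattr__(self, "hub_ids", tuple(self.hub_ids))
        object.__setattr__(self, "sensory_ids", tuple(self.sensory_ids))


def _module_of(spec: SyntheticConnectomeSpec) -> np.ndarray:
    block = int(np.ceil(spec.n_regions / spec.n_modules))
    return np.arange(spec.n_regions) // block


def _module_centers(n_modules: int) -> np.ndarray:
    # deterministic well-separated centers on a coarse 3-D lattice (mm)
    grid = int(np.ceil(n_modules ** (1 / 3)))
    pts = np.array(
        [(i, j, k) for i in range(grid) for j in range(grid) for k in range(grid)],
        dtype=float,
    )
    return 40.0 * pts[:n_modules]


def generate_connectome(spec: SyntheticConnectomeSpec) -> Connectome:
    """Generate a connected modular connectome with hub/sensory structure.

    Postconditions (verified before returning): symmetric, non-negative,
    zero-diagonal; each hub's strength above the 90th percentile with the
    overall maximum attained by a hub; each sensory node below the 25th
    percentile; single connected component; module-clustered coordinates.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_regions
    ids = default_region_ids(n)
    modules = _module_of(spec)
    hub_idx = np.array([ids.index(r) for r in spec.hub_ids], dtype=int)
    sens_idx = np.array([ids.index(r) for r in spec.sensory_ids], dtype=int)

    gains = rng.lognormal(mean=0.0, sigma=spec.gain_sigma, size=n)
    plain = np.ones(n, dtype=bool)
    plain[hub_idx] = plain[sens_idx] = False
    gains[hub_idx] = spec.hub_boost * gains[plain].max()
    gains[sens_idx] = spec.sensory_damp * gains[plain].min()

    same = modules[:, None] == modules[None, :]
    p = np.where(same, spec.p_intra, spec.p_inter)
    # attachment probability follows the endpoint gains as well
    pref = np.sqrt(np.outer(gains, gains) / np.median(gains) ** 2)
    p = np.clip(p * pref, 0.0, 1.0)

    iu, ju = np.triu_indices(n, k=1)
    present = rng.random(iu.size) < p[iu, ju]
    raw_w = rng.lognormal(spec.weight_location, spec.weight_scale, size=iu.size)
    edge_gain = np.sqrt(gains[iu] * gains[ju])
    w = np.zeros((n, n))
    vals = np.where(present, raw_w * edge_gain, 0.0)
    w[iu, ju] = vals
    w[ju, iu] = vals

    # deterministically bridge any disconnected components through a hub
    n_comp, labels = connected_components(w > 0, directed=False)
    if n_comp > 1:
        anchor = hub_idx[0]
        med = np.median(vals[vals > 0]) if np.any(vals > 0) else 1.0
        for comp in range(n_comp):
            if labels[comp == labels].size and comp != labels[anchor]:
                member = int(np.flatnonzero(labels == comp)[0])
                w[anchor, member] = w[member, anchor] = med

    centers = _module_centers(spec.n_modules)
    xyz = centers[modules] + rng.normal(scale=8.0, size=(n, 3))

    conn = Connectome(w, ids, coordinates=xyz)
    _check_contracts(conn, hub_idx, sens_idx)
    return conn


def _check_contracts(conn: Connectome, hub_idx, sens_idx) -> None:
    s = conn.weights.sum(axis=0)
    q90, q25 = np.percentile(s, [90, 25])
    if not np.all(s[hub_idx] > q90):
        raise RuntimeError("generator contract violated: hub below 90th percentile")
    if int(np.argmax(s)) not in set(hub_idx.tolist()):
        raise RuntimeError("generator contract violated: maximum strength not a hub")
    if not np.all(s[sens_idx] < q25):
        raise RuntimeError(
            "generator contract violated: sensory node above 25th percentile"
        )
    n_comp, _ = connected_components(conn.weights > 0, directed=False)
    if n_comp != 1:
        raise RuntimeError("generator contract violated: graph not connected")


@dataclasses.dataclass(frozen=True)
class SyntheticBoldSpec:
    """Sinusoids-plus-noise fixture for amplitude/connectivity metrics."""

    n_signals: int = 4
    duration: float = 300.0
    sampling_interval: float = 2.25
    component_freqs: Sequence[float] = (0.05,)
    component_amps: Sequence[float] = (1.0,)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0 or self.sampling_interval <= 0:
            raise ValueError("duration and sampling_interval must be positive")
        if len(self.component_freqs) != len(self.component_amps):
            raise ValueError("component_freqs and component_amps differ in length")
        nyq = 1.0 / (2.0 * self.sampling_interval)
        for f in self.component_freqs:
            if f > nyq:
                raise ValueError(f"component at {f} Hz exceeds Nyquist {nyq} Hz")


def generate_bold(spec: SyntheticBoldSpec) -> np.ndarray:
    """Band-limited signals: sum of sinusoids with per-signal random phase
    plus white Gaussian noise.  Shape ``(n_signals, floor(duration/dt))``."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(int(np.floor(spec.duration / spec.sampling_interval)))
    t = t * spec.sampling_interval
    x = np.zeros((spec.n_signals, t.size))
    for f, a in zip(spec.component_freqs, spec.component_amps):
        phi = rng.uniform(0, 2 * np.pi, size=spec.n_signals)
        x += a * np.sin(2 * np.pi * f * t[None, :] + phi[:, None])
    if spec.noise_sd > 0:
        x += rng.normal(scale=spec.noise_sd, size=x.shape)
    return x


def generate_reference_fc(
    conn: Connectome,
    omega: pd.Series,
    coupling_true: float,
    config: SimulationConfig,
    targets: Sequence[str],
    n_trials: int = 16,
    seed: int = 0,
    scale: str = "z",
) -> dict:
    """Model-generated reference seed-FC vectors for calibration recovery.

    Runs ``n_trials`` baseline simulations at the true coupling and
    returns ``{target: mean seed-FC Series}`` (Fisher-z averaged by
    default), to serve as ground truth when testing that the calibration
    procedure recovers the coupling that produced the data.
    """
    from .experiment import baseline_seed_fc_trials

    cfg = dataclasses.replace(config, coupling=float(coupling_true))
    trials = baseline_seed_fc_trials(conn, omega, cfg, targets, n_trials, seed)
    from .metrics import average_fc

    out = {}
    for tgt, mat in trials.items():
        other = [r for r in conn.region_ids if r != tgt]
        out[tgt] = pd.Series(average_fc(mat, method=scale), index=other, name=tgt)
    return out
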