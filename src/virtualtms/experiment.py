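"""Virtual-inhibition experiments on the oscillator model.

Inhibitory stimulation of a region is modelled as a reduction of its
natural frequency by ``delta_omega``.  Each trial runs a baseline and a
perturbed simulation from *identical* random initial phases (a paired
design: with ``delta_omega = 0`` the pre and post runs are bitwise equal,
so every downstream change statistic is exactly null).  Trial seeds are
derived as ``base_seed + trial_index``, making results independent of
execution order.

Changes in the target's seed-based functional connectivity are swept over
a grid of frequency reductions, aggregated as mean +/- s.e.m. across
trials, tested region-by-region with the Wilcoxon signed-rank test under
Bonferroni correction, and compared against control-site perturbations.
Coupling is calibrated by maximizing the pattern correlation between
simulated and reference baseline seed-FC.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .connectome import Connectome
from .kuramoto import SimulationConfig, draw_initial_phases, integrate_batch
from .metrics import RankTestResult, bonferroni, paired_rank_test, Z_CLIP

__all__ = [
    "PerturbationSpec",
    "TrialPair",
    "SweepResult",
    "PerRegionStats",
    "ControlSiteResult",
    "CalibrationResult",
    "run_trial_pair",
    "run_trials",
    "sweep_delta_omega",
    "peak_delta",
    "per_region_stats",
    "control_site_experiment",
    "calibrate_lambda",
    "baseline_seed_fc_trials",
]


class PerturbationError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class PerturbationSpec:
    """Slow one region's natural frequency by ``delta_omega`` Hz."""

    target: str
    delta_omega: float

    def __post_init__(self):
        if self.delta_omega < 0:
            raise PerturbationError(
                f"delta_omega must be >= 0, got {self.delta_omega}"
            )


@dataclasses.dataclass(frozen=True)
class TrialPair:
    """Baseline and perturbed seed-FC vectors from one shared-seed trial."""

    pre_fc: pd.Series
    post_fc: pd.Series
    seed: int

    def __post_init__(self):
        if len(self.pre_fc) != len(self.post_fc):
            raise ValueError("pre and post seed-FC vectors differ in length")


@dataclasses.dataclass(frozen=True)
class SweepResult:
    """Aggregated FC change across a grid of frequency reductions."""

    target: str
    deltas: np.ndarray
    mean_change: np.ndarray
    sem: np.ndarray
    per_region: pd.DataFrame  # rows: deltas, columns: non-target regions
    trial_means: np.ndarray  # (n_deltas, n_trials) per-trial region-mean changes
    n_trials: int
    scale: str  # "z" (Fisher) or "raw" correlation units

    def __post_init__(self):
        d = np.asarray(self.deltas, dtype=float)
        if d.size == 0:
            raise ValueError("empty delta grid")
        if d.size > 1 and np.any(np.diff(d) <= 0):
            raise ValueError("delta grid must be strictly increasing")
        if np.any(np.asarray(self.sem) < 0):
            raise ValueError("sem must be non-negative")


@dataclasses.dataclass(frozen=True)
class PerRegionStats:
    """Signed-rank table over non-target regions with Bonferroni decision."""

    table: pd.DataFrame  # columns: statistic, p_value, n_effective, significant
    alpha: float
    threshold: float


@dataclasses.dataclass(frozen=True)
class ControlSiteResult:
    sweeps: Dict[str, SweepResult]
    pair_change: Dict[str, float]  # control -> mean change in FC(sensory, hub)
    pair_test: Dict[str, RankTestResult]


@dataclasses.dataclass(frozen=True)
class CalibrationResult:
    lambda_grid: np.ndarray
    fit_r: np.ndarray
    selected_lambda: float

    def __post_init__(self):
        i = int(np.argmax(self.fit_r))
        if self.selected_lambda != self.lambda_grid[i]:
            raise ValueError("selected_lambda must attain the maximal fit")


# ---------------------------------------------------------------------------
# batched simulation helpers


def _aligned_omega(conn: Connectome, omega: pd.Series) -> np.ndarray:
    vals = omega.reindex(list(conn.region_ids))
    if vals.isna().any():
        missing = list(vals.index[vals.isna()])
        raise ValueError(f"frequency profile missing regions: {missing}")
    return vals.to_numpy(dtype=float)


def _trial_phase_matrix(n_regions: int, base_seed: int, n_trials: int) -> np.ndarray:
    cols = [draw_initial_phases(n_regions, base_seed + i) for i in range(n_trials)]
    return np.stack(cols, axis=1)


def _ensemble_signals(
    conn: Connectome,
    omega_hz: np.ndarray,
    config: SimulationConfig,
    theta0: np.ndarray,
) -> np.ndarray:
    """Sampled BOLD-proxy signals sin(theta), shape (N, T, B)."""
    omega_rad = config.angular_rate(omega_hz)
    if omega_rad.ndim == 1:
        omega_rad = np.repeat(omega_rad[:, None], theta0.shape[1], axis=1)
    phases = integrate_batch(conn.weights, omega_rad, theta0, config)
    return np.sin(phases)


def _ensemble_seed_fc(x: np.ndarray, target_idx: int) -> np.ndarray:
    """Per-trial target-to-rest correlations from signals (N, T, B).

    Returns shape (B, N-1), target column removed, rows ordered by region.
    """
    xc = x - x.mean(axis=1, keepdims=True)
    norm = np.sqrt((xc**2).sum(axis=1))
    if np.any(norm == 0):
        raise FloatingPointError("constant simulated series; cannot correlate")
    xn = xc / norm[:, None, :]
    r = np.einsum("ntb,tb->nb", xn, xn[target_idx])
    r = np.clip(r, -1.0, 1.0)
    keep = np.arange(x.shape[0]) != target_idx
    return r[keep].T


def _ensemble_pair_fc(x: np.ndarray, i: int, j: int) -> np.ndarray:
    """Per-trial correlation between regions i and j, shape (B,)."""
    xi = x[i] - x[i].mean(axis=0, keepdims=True)
    xj = x[j] - x[j].mean(axis=0, keepdims=True)
    denom = np.sqrt((xi**2).sum(axis=0) * (xj**2).sum(axis=0))
    return np.clip((xi * xj).sum(axis=0) / denom, -1.0, 1.0)


def _on_scale(r: np.ndarray, scale: str) -> np.ndarray:
    if scale == "raw":
        return r
    if scale == "z":
        return np.arctanh(np.clip(r, -1 + Z_CLIP, 1 - Z_CLIP))
    raise ValueError(f"unknown scale {scale!r}")


def baseline_seed_fc_trials(
    conn: Connectome,
    omega: pd.Series,
    config: SimulationConfig,
    targets: Sequence[str],
    n_trials: int,
    base_seed: int,
) -> Dict[str, np.ndarray]:
    """Unperturbed trials; per-target arrays of seed-FC vectors (B, N-1)."""
    omega_hz = _aligned_omega(conn, omega)
    theta0 = _trial_phase_matrix(conn.n_regions, base_seed, n_trials)
    x = _ensemble_signals(conn, omega_hz, config, theta0)
    return {t: _ensemble_seed_fc(x, conn.index_of(t)) for t in targets}


# ---------------------------------------------------------------------------
# trials and sweeps


def _perturbed_omega(
    conn: Connectome, omega_hz: np.ndarray, perturbation: PerturbationSpec
) -> np.ndarray:
    idx = conn.index_of(perturbation.target)
    # tolerate float rounding when the reduction equals the target frequency
    if omega_hz[idx] - perturbation.delta_omega < -1e-12:
        raise PerturbationError(
            f"delta_omega={perturbation.delta_omega} would drive "
            f"{perturbation.target} below zero frequency "
            f"(omega={omega_hz[idx]})"
        )
    out = omega_hz.copy()
    out[idx] = max(0.0, out[idx] - perturbation.delta_omega)
    return out


def run_trials(
    conn: Connectome,
    omega: pd.Series,
    config: SimulationConfig,
    perturbation: PerturbationSpec,
    n_trials: int,
    base_seed: int,
) -> List[TrialPair]:
    """Paired baseline/perturbed trials sharing initial phases per trial."""
    omega_hz = _aligned_omega(conn, omega)
    omega_post = _perturbed_omega(conn, omega_hz, perturbation)
    theta0 = _trial_phase_matrix(conn.n_regions, base_seed, n_trials)
    t_idx = conn.index_of(perturbation.target)
    pre = _ensemble_seed_fc(
        _ensemble_signals(conn, omega_hz, config, theta0), t_idx
    )
    post = _ensemble_seed_fc(
        _ensemble_signals(conn, omega_post, config, theta0), t_idx
    )
    other = [r for r in conn.region_ids if r != perturbation.target]
    return [
        TrialPair(
            pre_fc=pd.Series(pre[i], index=other),
            post_fc=pd.Series(post[i], index=other),
            seed=base_seed + i,
        )
        for i in range(n_trials)
    ]


def run_trial_pair(
    conn: Connectome,
    omega: pd.Series,
    config: SimulationConfig,
    perturbation: PerturbationSpec,
    trial_seed: int,
) -> TrialPair:
    """One paired trial (see :func:`run_trials`)."""
    return run_trials(conn, omega, config, perturbation, 1, trial_seed)[0]


def sweep_delta_omega(
    conn: Connectome,
    omega: pd.Series,
    config: SimulationConfig,
    target: str,
    deltas,
    n_trials: int,
    base_seed: int,
    scale: str = "z",
) -> SweepResult:
    """Sweep the frequency reduction and aggregate seed-FC changes.

    Trial seeds (hence initial phases and the baseline runs) are shared
    across grid points, so the baseline ensemble is simulated once and the
    sweep curve is differenced against it point by point.
    """
    deltas = np.asarray(deltas, dtype=float)
    if n_trials < 2:
        raise ValueError("need n_trials >= 2 for a s.e.m.")
    omega_hz = _aligned_omega(conn, omega)
    t_idx = conn.index_of(target)
    if np.any(deltas < 0) or np.any(deltas > omega_hz[t_idx] + 1e-12):
        raise PerturbationError(
            f"deltas must lie in [0, omega_target={omega_hz[t_idx]:.4g}]"
        )
    theta0 = _trial_phase_matrix(conn.n_regions, base_seed, n_trials)
    pre = _ensemble_seed_fc(
        _ensemble_signals(conn, omega_hz, config, theta0), t_idx
    )
    pre_s = _on_scale(pre, scale)
    other = [r for r in conn.region_ids if r != target]
    mean_change = np.empty(deltas.size)
    sem = np.empty(deltas.size)
    per_region = np.empty((deltas.size, len(other)))
    all_trial_means = np.empty((deltas.size, n_trials))
    for k, d in enumerate(deltas):
        if d == 0.0:
            diff = np.zeros_like(pre_s)  # paired null is exact by design
        else:
            pert = PerturbationSpec(target=target, delta_omega=float(d))
            omega_post = _perturbed_omega(conn, omega_hz, pert)
            post = _ensemble_seed_fc(
                _ensemble_signals(conn, omega_post, config, theta0), t_idx
            )
            diff = _on_scale(post, scale) - pre_s
        trial_means = diff.mean(axis=1)
        all_trial_means[k] = trial_means
        mean_change[k] = trial_means.mean()
        sem[k] = (
            trial_means.std(ddof=1) / np.sqrt(n_trials) if n_trials > 1 else 0.0
        )
        per_region[k] = diff.mean(axis=0)
    return SweepResult(
        target=target,
        deltas=deltas,
        mean_change=mean_change,
        sem=sem,
        per_region=pd.DataFrame(per_region, index=deltas, columns=other),
        trial_means=all_trial_means,
        n_trials=n_trials,
        scale=scale,
    )


def peak_delta(sweep: SweepResult) -> float:
    """Grid value with maximal mean FC change (ties: smallest delta)."""
    return float(sweep.deltas[int(np.argmax(sweep.mean_change))])


def per_region_stats(trials: List[TrialPair], alpha: float = 0.05) -> PerRegionStats:
    """Signed-rank test of pre vs post seed-FC per region, Bonferroni-corrected.

    Regions whose differences are all zero (e.g. a null perturbation) are
    reported as "no change": statistic 0, p = 1, not significant.
    """
    if len(trials) < 5:
        raise ValueError(f"need >= 5 trials, got {len(trials)}")
    regions = list(trials[0].pre_fc.index)
    pre = np.stack([t.pre_fc.to_numpy() for t in trials])
    post = np.stack([t.post_fc.to_numpy() for t in trials])
    rows = []
    for j, region in enumerate(regions):
        if np.all(post[:, j] == pre[:, j]):
            rows.append((region, 0.0, 1.0, 0))
        else:
            res = paired_rank_test(pre[:, j], post[:, j])
            rows.append((region, res.statistic, res.p_value, res.n_effective))
    table = pd.DataFrame(
        rows, columns=["region", "statistic", "p_value", "n_effective"]
    ).set_index("region")
    mask, threshold = bonferroni(table["p_value"].to_numpy(), alpha=alpha)
    table["significant"] = mask
    return PerRegionStats(table=table, alpha=alpha, threshold=threshold)


def control_site_experiment(
    conn: Connectome,
    omega: pd.Series,
    config: SimulationConfig,
    control_targets: Sequence[str],
    sensory_id: str,
    hub_id: str,
    delta_omega: float = 0.001,
    n_trials: int = 20,
    base_seed: int = 0,
    scale: str = "z",
) -> ControlSiteResult:
    """Perturb hypothesis-irrelevant control sites.

    For each control region, runs paired trials at one frequency
    reduction, aggregates its own seed-FC change as a single-point sweep,
    and additionally tracks the sensory-hub FC pair across trials (the
    quantity the controls should leave unmodulated).
    """
    designated = {sensory_id, hub_id}
    for c in control_targets:
        if c in designated:
            raise ValueError(f"control target {c!r} is a designated region")
        conn.index_of(c)  # raises on unknown id
    omega_hz = _aligned_omega(conn, omega)
    theta0 = _trial_phase_matrix(conn.n_regions, base_seed, n_trials)
    si, hi = conn.index_of(sensory_id), conn.index_of(hub_id)
    x_pre = _ensemble_signals(conn, omega_hz, config, theta0)
    pair_pre = _ensemble_pair_fc(x_pre, si, hi)
    sweeps, pair_change, pair_test = {}, {}, {}
    for c in control_targets:
        c_idx = conn.index_of(c)
        pert = PerturbationSpec(target=c, delta_omega=delta_omega)
        if delta_omega == 0.0:
            x_post = x_pre
        else:
            omega_post = _perturbed_omega(conn, omega_hz, pert)
            x_post = _ensemble_signals(conn, omega_post, config, theta0)
        pre = _ensemble_seed_fc(x_pre, c_idx)
        post = _ensemble_seed_fc(x_post, c_idx)
        diff = _on_scale(post, scale) - _on_scale(pre, scale)
        trial_means = diff.mean(axis=1)
        other = [r for r in conn.region_ids if r != c]
        sweeps[c] = SweepResult(
            target=c,
            deltas=np.array([delta_omega]),
            mean_change=np.array([trial_means.mean()]),
            sem=np.array(
                [trial_means.std(ddof=1) / np.sqrt(n_trials) if n_trials > 1 else 0.0]
            ),
            per_region=pd.DataFrame(
                diff.mean(axis=0)[None, :], index=[delta_omega], columns=other
            ),
            trial_means=trial_means[None, :],
            n_trials=n_trials,
            scale=scale,
        )
        pair_post = _ensemble_pair_fc(x_post, si, hi)
        d = _on_scale(pair_post, scale) - _on_scale(pair_pre, scale)
        pair_change[c] = float(d.mean())
        if np.all(d == 0):
            pair_test[c] = RankTestResult(statistic=0.0, p_value=1.0, n_effective=0)
        else:
            pair_test[c] = paired_rank_test(
                _on_scale(pair_pre, scale), _on_scale(pair_post, scale)
            )
    return ControlSiteResult(
        sweeps=sweeps, pair_change=pair_change, pair_test=pair_test
    )


def calibrate_lambda(
    conn: Connectome,
    omega: pd.Series,
    config: SimulationConfig,
    reference_fc: Dict[str, pd.Series],
    lambda_grid,
    n_trials: int = 16,
    base_seed: int = 0,
    scale: str = "z",
) -> CalibrationResult:
    """Select the coupling maximizing the fit to reference baseline seed-FC.

    For each grid value, simulates ``n_trials`` baselines (trial seeds
    shared across the grid), averages each target's seed-FC vector, and
    scores the Pearson correlation with the reference vector; the fit is
    the mean over targets and the smallest maximizing coupling is
    selected.
    """
    grid = np.asarray(lambda_grid, dtype=float)
    if grid.size == 0 or np.any(grid <= 0):
        raise ValueError("lambda_grid must be non-empty and positive")
    refs = {}
    for tgt, vec in reference_fc.items():
        v = np.asarray(vec, dtype=float)
        if v.std() == 0:
            raise ValueError(f"degenerate reference FC for target {tgt!r}")
        refs[tgt] = v
    from .metrics import average_fc

    fit_r = np.empty(grid.size)
    for k, lam in enumerate(grid):
        cfg = dataclasses.replace(config, coupling=float(lam))
        per_target = baseline_seed_fc_trials(
            conn, omega, cfg, list(refs), n_trials, base_seed
        )
        rs = []
        for tgt, ref in refs.items():
            mean_vec = average_fc(per_target[tgt], method=scale)
            rs.append(np.corrcoef(mean_vec, ref)[0, 1])
        fit_r[k] = float(np.mean(rs))
    best = int(np.argmax(fit_r))  # first max -> smallest lambda on ties
    return CalibrationResult(
        lambda_grid=grid, fit_r=fit_r, selected_lambda=float(grid[best])
    )
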