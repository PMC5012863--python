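"""Functional-connectivity and amplitude metrics, with paired statistics.

Functional connectivity (FC) is the Pearson correlation between regional
time series; seed FC is one region's correlation with every other region.
ALFF is the mean amplitude-spectrum value within a low-frequency band
(default 0.01-0.1 Hz).  Pre/post comparisons use the two-sided Wilcoxon
signed-rank test with Bonferroni correction across regions.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .kuramoto import ObservableSeries

__all__ = [
    "ConstantSeriesError",
    "fc_matrix",
    "seed_fc",
    "fisher_z",
    "average_fc",
    "alff",
    "RankTestResult",
    "paired_rank_test",
    "bonferroni",
    "correlate_changes",
]

#: correlations are clipped to +/- (1 - Z_CLIP) before atanh when averaging,
#: so numerically perfect correlations do not produce infinite z-values
Z_CLIP = 1e-12


class ConstantSeriesError(ValueError):
    """A time series has zero variance, so correlation is undefined."""


def _as_matrix(series) -> tuple[np.ndarray, list]:
    if isinstance(series, ObservableSeries):
        return np.asarray(series.values, dtype=float), list(series.region_ids)
    if isinstance(series, pd.DataFrame):
        return series.to_numpy(dtype=float).T, list(series.columns)
    x = np.asarray(series, dtype=float)
    return x, [f"r{i}" for i in range(x.shape[0])]


def fc_matrix(series, region_ids=None) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix of regional time series.

    Accepts an :class:`~virtualtms.kuramoto.ObservableSeries`, a
    ``(time, region)`` DataFrame, or a plain ``(region, time)`` array.
    """
    x, ids = _as_matrix(series)
    if region_ids is not None:
        ids = list(region_ids)
    if x.ndim != 2 or x.shape[1] < 3:
        raise ValueError("need a 2-D series matrix with >= 3 time points")
    const = np.ptp(x, axis=1) == 0
    if np.any(const):
        bad = [ids[i] for i in np.flatnonzero(const)]
        raise ConstantSeriesError(f"constant time series for regions: {bad}")
    r = np.corrcoef(x)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(np.clip(r, -1.0, 1.0), index=ids, columns=ids)


def seed_fc(fc: pd.DataFrame, target) -> pd.Series:
    """The target region's correlations with every other region (length N-1)."""
    if target not in fc.index:
        raise KeyError(f"unknown region id: {target!r}")
    return fc.loc[target].drop(target)


def fisher_z(r):
    """Fisher z-transform, z = atanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def average_fc(fc_vectors, method: str = "z") -> np.ndarray:
    """Average correlation vectors across trials.

    ``method="z"`` (default) averages on the Fisher-z scale and transforms
    back; ``"raw"`` averages the correlations directly.  Values are
    clipped to ``1 - Z_CLIP`` in magnitude before the transform.
    """
    r = np.asarray(fc_vectors, dtype=float)
    if method == "raw":
        return r.mean(axis=0)
    if method == "z":
        return np.tanh(np.arctanh(np.clip(r, -1 + Z_CLIP, 1 - Z_CLIP)).mean(axis=0))
    raise ValueError(f"unknown averaging method {method!r}")


def alff(series, sampling_interval: float = None, band=(0.01, 0.1)) -> pd.Series:
    """Amplitude of low-frequency fluctuations per region.

    The one-sided amplitude spectrum of the demeaned series is
    ``A_k = (2/T) |sum_t x_t exp(-2*pi*i*k*t/T)|`` at frequency
    ``f_k = k / (T * dt)``; ALFF is the mean of ``A_k`` over bins with
    ``band[0] <= f_k <= band[1]``.  The DC bin is excluded since the band
    starts above zero, so ALFF is invariant to constant offsets.
    """
    if isinstance(series, ObservableSeries):
        if sampling_interval is None:
            dts = np.diff(series.times)
            sampling_interval = float(dts[0])
        x, ids = np.asarray(series.values, float), list(series.region_ids)
    else:
        if sampling_interval is None:
            raise ValueError("sampling_interval required for plain arrays")
        x, ids = _as_matrix(series)
    low, high = band
    if not 0 < low < high:
        raise ValueError(f"band must satisfy 0 < low < high, got {band}")
    nyquist = 1.0 / (2.0 * sampling_interval)
    if high > nyquist:
        raise ValueError(f"band upper edge {high} Hz exceeds Nyquist {nyquist} Hz")
    t = x.shape[1]
    freqs = np.fft.rfftfreq(t, d=sampling_interval)
    in_band = (freqs >= low) & (freqs <= high)
    if in_band.sum() < 2:
        raise ValueError(
            f"band {band} contains {in_band.sum()} DFT bins at length {t}; "
            f"need >= 2 (frequency resolution {freqs[1]:.4g} Hz)"
        )
    spec = np.abs(np.fft.rfft(x - x.mean(axis=1, keepdims=True), axis=1)) * 2.0 / t
    return pd.Series(spec[:, in_band].mean(axis=1), index=ids, name="alff")


@dataclasses.dataclass(frozen=True)
class RankTestResult:
    """Two-sided Wilcoxon signed-rank outcome for one paired comparison."""

    statistic: float  # W+, the sum of ranks of positive differences
    p_value: float
    n_effective: int  # pairs remaining after dropping zero differences


#: largest n for which the exact null distribution is enumerated
EXACT_N_MAX = 25


def _exact_signed_rank_p(ranks2: np.ndarray, w2: int) -> float:
    # null distribution of 2*W+ by subset-sum convolution over the doubled
    # (hence integer) mid-ranks; equivalent to enumerating all 2^n sign
    # assignments
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    counts /= counts.sum()
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def paired_rank_test(pre, post, mode: str = "auto") -> RankTestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; tied absolute differences receive
    mid-ranks.  ``mode="auto"`` enumerates the exact null when the
    effective sample size is at most ``EXACT_N_MAX`` and otherwise uses a
    normal approximation with continuity and tie corrections; ``"exact"``
    and ``"approx"`` force either path.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be 1-D arrays of equal length")
    if pre.size < 5:
        raise ValueError(f"need >= 5 pairs, got {pre.size}")
    d = post - pre
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero; the test is undefined")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if mode not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}")
    use_exact = mode == "exact" or (mode == "auto" and n <= EXACT_N_MAX)
    if use_exact:
        ranks2 = np.rint(2 * ranks)  # mid-ranks doubled to integers
        p = _exact_signed_rank_p(ranks2, int(round(2 * w_plus)))
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
        dev = w_plus - mean
        # continuity correction shrinks the deviation by half a rank unit
        z = (dev - 0.5 * np.sign(dev)) / np.sqrt(var)
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return RankTestResult(statistic=w_plus, p_value=p, n_effective=n)


def bonferroni(p_values, alpha: float = 0.05):
    """Bonferroni decision: test i is significant iff p_i < alpha / m.

    Returns ``(mask, threshold)``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    threshold = alpha / p.size
    return p < threshold, threshold


def correlate_changes(delta_a, delta_b):
    """Pearson correlation between two vectors of paired changes.

    Returns ``(r, p)`` with a two-sided p-value from the t-distribution.
    """
    a = np.asarray(delta_a, dtype=float)
    b = np.asarray(delta_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("need equal-length 1-D vectors with >= 3 entries")
    if a.std() == 0 or b.std() == 0:
        raise ConstantSeriesError("zero variance in a change vector")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)
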