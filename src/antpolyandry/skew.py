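"""Paternity skew indices and their Monte-Carlo nulls.

Two indices are used.  The binomial B-index (Nonacs) measures the
deviation of paternity shares from a uniform multinomial expectation,

    B = sum_i (p_i - 1/k)^2 - (1 - 1/k)/n,

and has expectation zero under purely random (multinomial) allocation of
n workers to k patrilines; it is tested with one-tailed empirical
p-values from uniform-multinomial simulation.  The S-index (Pamilo)
rescales effective paternity, S = (k_obs - m_e)/(k_obs - 1): 0 for even
paternity, 1 for monopoly.  Because sampling alone inflates S, observed
values are compared against a case-specific Monte-Carlo null in which
each worker is equally likely to belong to any observed patriline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .estimators import (
    effective_paternity_corrected,
    effective_paternity_uncorrected,
)

__all__ = [
    "SkewStatistics",
    "b_index",
    "b_index_batch",
    "b_pvalue",
    "s_index",
    "s_null_interval",
    "skew_statistics",
]


@dataclass
class SkewStatistics:
    """Skew summary for one colony."""

    colony_id: str
    B: Optional[float]
    p_high: Optional[float]
    p_low: Optional[float]
    S: Optional[float]
    S_clamped: bool
    S_null_low: Optional[float]
    S_null_high: Optional[float]
    S_significant: Optional[bool]
    n_sims_B: int
    n_sims_S: int
    seed: int


def b_index(counts: Sequence[int]) -> Optional[float]:
    """Nonacs' binomial skew index with equal expected shares.

    Returns None (undefined) for a single patriline.
    """
    counts = np.asarray(counts, dtype=float)
    k = counts.size
    if k < 2:
        return None
    n = counts.sum()
    if n <= 0:
        raise ValueError("no workers")
    p = counts / n
    return float(np.sum((p - 1.0 / k) ** 2) - (1.0 - 1.0 / k) / n)


def b_index_batch(count_matrix: np.ndarray) -> np.ndarray:
    """B-index per row of a (draws, k) count matrix (vectorized)."""
    counts = np.asarray(count_matrix, dtype=float)
    k = counts.shape[1]
    n = counts.sum(axis=1)
    p = counts / n[:, None]
    return np.sum((p - 1.0 / k) ** 2, axis=1) - (1.0 - 1.0 / k) / n


def b_pvalue(
    counts: Sequence[int], n_sims: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """One-tailed empirical p-values for the B-index.

    Simulates ``n_sims`` uniform multinomial allocations of the same n
    workers to the same k patrilines; p_high is the fraction of
    simulations with B at least as large as observed (skew), p_low the
    fraction at most as large (excess evenness).  Add-one smoothing
    keeps p-values away from exact zero.
    """
    counts = np.asarray(counts, dtype=int)
    k = counts.size
    if k < 2:
        raise ValueError("B-index p-value needs >= 2 patrilines")
    n = int(counts.sum())
    b_obs = b_index(counts)
    rng = np.random.default_rng(seed)
    sims = rng.multinomial(n, np.full(k, 1.0 / k), size=n_sims)
    b_sim = b_index_batch(sims)
    p_high = (np.sum(b_sim >= b_obs) + 1.0) / (n_sims + 1.0)
    p_low = (np.sum(b_sim <= b_obs) + 1.0) / (n_sims + 1.0)
    return float(p_high), float(p_low)


def s_index(k_obs: int, m_e: float) -> tuple[Optional[float], bool]:
    """Pamilo's effective-number skew index S = (k_obs - m_e)/(k_obs - 1).

    Returns (S, clamped).  Negative values — possible when a corrected
    m_e exceeds k_obs — are conservatively clamped to zero skew and
    flagged.  Undefined (None) for k_obs < 2.
    """
    if k_obs < 2:
        return None, False
    s = (k_obs - m_e) / (k_obs - 1.0)
    if s < 0.0:
        return 0.0, True
    return float(s), False


def _null_s_draws(
    n: int, k_obs: int, estimator: str, n_iters: int, rng: np.random.Generator
) -> np.ndarray:
    """S-values from uniform random assignment of n workers to k_obs
    patrilines (negatives clamped to zero, as for observed values)."""
    counts = rng.multinomial(n, np.full(k_obs, 1.0 / k_obs), size=n_iters)
    out = np.empty(n_iters)
    if estimator == "uncorrected":
        p = counts / n
        m_e = 1.0 / np.sum(p * p, axis=1)
    elif estimator == "corrected":
        p = counts / n
        denom = (n + 1.0) * (n - 2.0) * np.sum(p * p, axis=1) + 3.0 - n
        with np.errstate(divide="ignore"):
            m_e = np.where(denom > 0, (n - 1.0) ** 2 / denom, np.nan)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    out = (k_obs - m_e) / (k_obs - 1.0)
    out = np.where(np.isnan(out), 0.0, out)
    return np.clip(out, 0.0, None)


def s_null_interval(
    n: int,
    k_obs: int,
    estimator: str = "corrected",
    n_iters: int = 3000,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """95% Monte-Carlo null interval for the S-index.

    Returns (low, high, draws): the 2.5th and 97.5th percentiles
    (linear-interpolation percentiles) of S under uniform random
    allocation, plus the raw null draws for downstream use (e.g. the
    randomized-slope interval of the comparative analyses).
    """
    if k_obs < 2:
        raise ValueError("null interval needs k_obs >= 2")
    if n < k_obs:
        raise ValueError("n must be >= k_obs")
    rng = np.random.default_rng(seed)
    draws = _null_s_draws(n, k_obs, estimator, n_iters, rng)
    low, high = np.percentile(draws, [2.5, 97.5], method="linear")
    return float(low), float(high), draws


def skew_statistics(
    colony_id: str,
    counts: Sequence[int],
    estimator: str = "corrected",
    n_sims_B: int = 1000,
    n_sims_S: int = 3000,
    seed: int = 0,
) -> SkewStatistics:
    """Full skew summary for one colony from patriline worker counts."""
    counts = [int(c) for c in counts]
    k_obs = len(counts)
    n = sum(counts)
    B = b_index(counts)
    if B is not None:
        p_high, p_low = b_pvalue(counts, n_sims=n_sims_B, seed=seed)
    else:
        p_high = p_low = None
    if k_obs >= 2:
        if estimator == "corrected":
            m_e = effective_paternity_corrected(counts)
            if m_e is None:
                m_e = effective_paternity_uncorrected(counts)
        else:
            m_e = effective_paternity_uncorrected(counts)
        S, clamped = s_index(k_obs, m_e)
        low, high, _ = s_null_interval(
            n, k_obs, estimator=estimator, n_iters=n_sims_S, seed=seed + 1
        )
        significant = bool(S < low or S > high)
    else:
        S, clamped, low, high, significant = None, False, None, None, None
    return SkewStatistics(
        colony_id=colony_id,
        B=B, p_high=p_high, p_low=p_low,
        S=S, S_clamped=clamped,
        S_null_low=low, S_null_high=high, S_significant=significant,
        n_sims_B=n_sims_B, n_sims_S=n_sims_S, seed=seed,
    )
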