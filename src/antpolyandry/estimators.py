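"""Paternity-frequency estimators and pedigree relatedness.

Three quantities summarize a colony's paternity: the observed patriline
count k_obs; the sample-size-corrected estimate k_est, which adds the
expected Poisson zero class k_obs * exp(-n/k_obs) for patrilines missed
by a finite worker sample; and the effective paternity m_e, the number
of equally contributing males that would yield the same worker-worker
relatedness as the observed, possibly skewed, shares.  m_e comes in an
uncorrected form 1/sum(p_i^2) (Starr) and a sample-size-corrected form
(Nielsen et al. 2003) that removes the upward bias of squared sample
proportions at small n.  Under outbreeding the expected pedigree
relatedness among haplodiploid sisters is g_ww = 0.25 + 0.5/m_e, which
is the reference value worker relatedness is tested against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PaternityEstimates",
    "SpeciesSummary",
    "estimate_paternity",
    "effective_paternity_uncorrected",
    "effective_paternity_corrected",
    "pedigree_relatedness",
    "paternity_estimates",
    "species_means",
    "round_half_up",
    "harmonic_mean",
    "jackknife_se",
]


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero, as printed tables conventionally do."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class PaternityEstimates:
    """Per-colony paternity summary (one row of a results table)."""

    colony_id: str
    n: int
    k_obs: int
    k_est: float
    m_e_uncorrected: float
    m_e_corrected: Optional[float]
    g_ww: float


@dataclass
class SpeciesSummary:
    """Species-level summary over colonies.

    Arithmetic means for patriline counts, harmonic mean for effective
    paternity (the relatedness-relevant average), delete-one jackknife
    SEs over colonies (None with a single colony).
    """

    species_id: str
    n_total: int
    k_obs_mean: float
    k_obs_se: Optional[float]
    k_est_mean: float
    k_est_se: Optional[float]
    m_e_harmonic: float
    m_e_se: Optional[float]


def estimate_paternity(k_obs: int, n: int) -> float:
    """Sample-size-corrected paternity frequency k_est.

    Per-patriline worker counts are modelled as Poisson with mean
    n/k_obs; the expected zero class k_obs * exp(-n/k_obs) estimates how
    many patrilines the sample missed, and is added back:
    k_est = k_obs * (1 + exp(-n/k_obs)).
    """
    if k_obs < 1:
        raise ValueError("k_obs must be >= 1")
    if n < k_obs:
        raise ValueError(f"n={n} < k_obs={k_obs}: impossible sample")
    return k_obs * (1.0 + math.exp(-n / k_obs))


def effective_paternity_uncorrected(counts: Sequence[int]) -> float:
    """Starr effective paternity: m_e = 1 / sum(p_i^2)."""
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty patriline counts")
    if np.any(counts < 0):
        raise ValueError("negative patriline count")
    n = counts.sum()
    if n <= 0:
        raise ValueError("no assigned workers")
    p = counts / n
    return float(1.0 / np.sum(p * p))


def effective_paternity_corrected(counts: Sequence[int]) -> Optional[float]:
    """Sample-size-corrected effective paternity (Nielsen et al.).

    m_e = (n-1)^2 / [ (n+1)(n-2) * sum(p_i^2) + 3 - n ].

    Unbiased for the true effective number of mates at large n; may
    exceed k_obs in small samples.  Undefined (None, with no exception)
    when the denominator is nonpositive or n < 3.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n < 3:
        return None
    p = counts / n
    denom = (n + 1.0) * (n - 2.0) * float(np.sum(p * p)) + 3.0 - n
    if denom <= 0:
        return None
    return float((n - 1.0) ** 2 / denom)


def pedigree_relatedness(m_e_uncorrected: float) -> float:
    """Expected worker-worker pedigree relatedness g_ww = 0.25 + 0.5/m_e."""
    if m_e_uncorrected < 1:
        raise ValueError("effective paternity must be >= 1")
    return 0.25 + 0.5 / m_e_uncorrected


def paternity_estimates(colony_id: str, counts: Sequence[int]) -> PaternityEstimates:
    """All per-colony paternity summaries from patriline worker counts."""
    counts = [int(c) for c in counts]
    if any(c < 1 for c in counts):
        raise ValueError("patriline counts must be >= 1")
    n = sum(counts)
    k_obs = len(counts)
    m_e_unc = effective_paternity_uncorrected(counts)
    return PaternityEstimates(
        colony_id=colony_id,
        n=n,
        k_obs=k_obs,
        k_est=estimate_paternity(k_obs, n),
        m_e_uncorrected=m_e_unc,
        m_e_corrected=effective_paternity_corrected(counts),
        g_ww=pedigree_relatedness(m_e_unc),
    )


def jackknife_se(values: Sequence[float]) -> Optional[float]:
    """Delete-one jackknife SE of the mean statistic over the values."""
    x = np.asarray(values, dtype=float)
    m = x.size
    if m < 2:
        return None
    loo = (x.sum() - x) / (m - 1)
    return float(np.sqrt((m - 1) / m * np.sum((loo - loo.mean()) ** 2)))


def harmonic_mean(values) -> float:
    """Harmonic mean (the relatedness-relevant average of m_e values)."""
    x = np.asarray(values, dtype=float)
    return float(x.size / np.sum(1.0 / x))


def species_means(
    species_id: str,
    estimates: Sequence[PaternityEstimates],
    which_m_e: str = "corrected",
) -> SpeciesSummary:
    """Species summary: arithmetic means of k_obs/k_est, harmonic mean of
    m_e, with delete-one jackknife SEs over colonies."""
    if not estimates:
        raise ValueError("no colonies")
    k_obs = np.array([e.k_obs for e in estimates], dtype=float)
    k_est = np.array([e.k_est for e in estimates], dtype=float)
    if which_m_e == "corrected":
        m_e = np.array(
            [e.m_e_corrected if e.m_e_corrected is not None else e.m_e_uncorrected
             for e in estimates]
        )
    elif which_m_e == "uncorrected":
        m_e = np.array([e.m_e_uncorrected for e in estimates])
    else:
        raise ValueError(f"unknown m_e choice {which_m_e!r}")

    def jack_harm(values: np.ndarray) -> Optional[float]:
        m = values.size
        if m < 2:
            return None
        loo = np.array([harmonic_mean(np.delete(values, i)) for i in range(m)])
        return float(np.sqrt((m - 1) / m * np.sum((loo - loo.mean()) ** 2)))

    return SpeciesSummary(
        species_id=species_id,
        n_total=int(sum(e.n for e in estimates)),
        k_obs_mean=float(k_obs.mean()),
        k_obs_se=jackknife_se(k_obs),
        k_est_mean=float(k_est.mean()),
        k_est_se=jackknife_se(k_est),
        m_e_harmonic=harmonic_mean(m_e),
        m_e_se=jack_harm(m_e),
    )
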