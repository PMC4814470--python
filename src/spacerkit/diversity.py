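"""Richness estimators (Chao1, ACE), diversity indices, and coverage.

Chao1 uses the classic estimator with the bias-corrected form when no
doubletons are present; its standard error follows the standard variance
formulas for each branch, and the 95% interval uses the log-normal
transformation on the estimated excess richness. ACE follows the standard
abundance-based coverage estimator with a rare-class cutoff of 10; its SE is a
delta-method approximation with numerical partial derivatives over the
frequency counts.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def _validate(counts: Sequence[int]) -> np.ndarray:
    arr = np.asarray(list(counts), dtype=np.int64)
    if arr.size == 0:
        raise ValueError("empty abundance vector")
    if (arr < 1).any():
        raise ValueError("all abundances must be >= 1")
    return arr


def good_coverage(counts: Sequence[int]) -> float:
    """Good's coverage: 1 - singletons / individuals."""
    arr = _validate(counts)
    return 1.0 - float(np.count_nonzero(arr == 1)) / float(arr.sum())


def chao1(counts: Sequence[int]) -> Tuple[float, float]:
    """Chao1 richness estimate and its standard error.

    Classic form S_obs + F1^2/(2 F2) when doubletons exist; bias-corrected
    S_obs + F1 (F1 - 1) / 2 otherwise.
    """
    arr = _validate(counts)
    s_obs = arr.size
    f1 = int(np.count_nonzero(arr == 1))
    f2 = int(np.count_nonzero(arr == 2))
    if f2 > 0:
        est = s_obs + f1 * f1 / (2.0 * f2)
        r = f1 / f2
        var = f2 * (r ** 2 / 2.0 + r ** 3 + r ** 4 / 4.0)
    else:
        est = s_obs + f1 * (f1 - 1) / 2.0
        if f1 > 0:
            var = (f1 * (f1 - 1) / 2.0 + f1 * (2 * f1 - 1) ** 2 / 4.0
                   - f1 ** 4 / (4.0 * est))
        else:
            var = 0.0
    return float(est), float(math.sqrt(max(var, 0.0)))


def chao1_interval(counts: Sequence[int], level: float = 0.95) -> Tuple[float, float]:
    """Log-normal confidence interval for Chao1 around S_obs + T/K .. S_obs + T*K."""
    arr = _validate(counts)
    s_obs = arr.size
    est, se = chao1(arr)
    t = est - s_obs
    if t <= 0 or se == 0:
        return float(s_obs), float(max(est, s_obs))
    z = 1.959963984540054 if abs(level - 0.95) < 1e-9 else _z_for(level)
    k = math.exp(z * math.sqrt(math.log(1.0 + se * se / (t * t))))
    return s_obs + t / k, s_obs + t * k


def _z_for(level: float) -> float:
    from statistics import NormalDist
    return NormalDist().inv_cdf(0.5 + level / 2.0)


def _ace_estimate_from_freqs(freqs: np.ndarray, s_abund: float, rare_cutoff: int) -> float:
    """ACE point estimate as a function of the rare frequency counts F1..F_cutoff."""
    i = np.arange(1, rare_cutoff + 1, dtype=float)
    s_rare = freqs.sum()
    n_rare = float((i * freqs).sum())
    f1 = float(freqs[0])
    if n_rare <= 0:
        return float(s_abund)
    c_ace = 1.0 - f1 / n_rare
    if c_ace <= 0:
        return float(s_abund + s_rare)
    if n_rare <= 1:
        gamma2 = 0.0
    else:
        gamma2 = max((s_rare / c_ace) * float((i * (i - 1) * freqs).sum())
                     / (n_rare * (n_rare - 1.0)) - 1.0, 0.0)
    return float(s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2)


def ace(counts: Sequence[int], rare_cutoff: int = 10) -> Tuple[float, float]:
    """ACE richness estimate and a delta-method standard error.

    Falls back to S_obs (with a logged warning) when the rare class is all
    singletons, where the sample coverage estimate is zero and ACE undefined.
    """
    arr = _validate(counts)
    s_obs = arr.size
    rare = arr[arr <= rare_cutoff]
    s_abund = int(np.count_nonzero(arr > rare_cutoff))
    f1 = int(np.count_nonzero(arr == 1))
    n_rare = int(rare.sum())
    if rare.size == 0:
        return float(s_obs), 0.0
    if n_rare == f1:
        logger.warning("ACE undefined (rare class is all singletons); falling back to S_obs")
        return float(s_obs), 0.0

    freqs = np.array([np.count_nonzero(arr == i) for i in range(1, rare_cutoff + 1)],
                     dtype=float)
    est = _ace_estimate_from_freqs(freqs, s_abund, rare_cutoff)

    # Delta method over F1..F_cutoff with multinomial-style covariance
    # cov(Fi, Fj) = Fi (delta_ij - Fj / S_hat); partials by central differences.
    grad = np.zeros_like(freqs)
    h = 1e-5
    for i in range(len(freqs)):
        up, dn = freqs.copy(), freqs.copy()
        up[i] += h
        dn[i] -= h
        grad[i] = (_ace_estimate_from_freqs(up, s_abund, rare_cutoff)
                   - _ace_estimate_from_freqs(dn, s_abund, rare_cutoff)) / (2 * h)
    s_hat = max(est, float(s_obs))
    cov = np.diag(freqs) - np.outer(freqs, freqs) / s_hat
    var = float(grad @ cov @ grad)
    return float(est), float(math.sqrt(max(var, 0.0)))


def shannon_simpson(counts: Sequence[int]) -> Tuple[float, float]:
    """Shannon index H = -sum p ln p and Simpson D = sum n(n-1) / (N(N-1))."""
    arr = _validate(counts)
    n = int(arr.sum())
    if n < 2:
        raise ValueError("Simpson index undefined for a single individual")
    p = arr / n
    h = float(-(p * np.log(p)).sum())
    d = float((arr * (arr - 1)).sum() / (n * (n - 1)))
    return h, d


def estimated_coverage_percent(s_obs: int, s_est: float) -> int:
    """round(100 * s_obs / s_est), ties half-up."""
    if s_obs <= 0:
        raise ValueError("s_obs must be positive")
    if s_est < s_obs:
        raise ValueError(f"s_est ({s_est}) < s_obs ({s_obs})")
    return int(math.floor(100.0 * s_obs / s_est + 0.5))


@dataclass
class RichnessEstimate:
    s_obs: int
    s_chao1: float
    se_chao1: float
    s_ace: float
    se_ace: float
    good_coverage: float
    coverage_percent: int
    shannon: float
    simpson: float


def richness_report(counts: Sequence[int]) -> RichnessEstimate:
    arr = _validate(counts)
    c1, se1 = chao1(arr)
    a1, sea = ace(arr)
    h, d = shannon_simpson(arr) if arr.sum() >= 2 else (0.0, float("nan"))
    return RichnessEstimate(
        s_obs=int(arr.size), s_chao1=c1, se_chao1=se1, s_ace=a1, se_ace=sea,
        good_coverage=good_coverage(arr),
        coverage_percent=estimated_coverage_percent(int(arr.size), max(c1, float(arr.size))),
        shannon=h, simpson=d)


def diversity_table(site_counts: dict) -> pd.DataFrame:
    """One row per site mirroring the shape of a sequencing-statistics table."""
    rows = []
    for site in sorted(site_counts):
        est = richness_report(site_counts[site])
        rows.append({
            "site": site, "n_spacers": int(np.asarray(site_counts[site]).sum()),
            "n_clusters": est.s_obs,
            "s_chao1": est.s_chao1, "se_chao1": est.se_chao1,
            "s_ace": est.s_ace, "se_ace": est.se_ace,
            "good_coverage": est.good_coverage,
            "coverage_percent": est.coverage_percent,
            "shannon": est.shannon, "simpson": est.simpson})
    return pd.DataFrame(rows)
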