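"""Model-adequacy layer: information criteria, distance statistics,
descriptive statistics and the TTT diagnostic.

The eight reported criteria are
tau1 = -2 log L, tau2 = AIC = tau1 + 2k, tau3 = AICc = tau2 + 2k(k+1)/(n-k-1),
tau4 = BIC = tau1 + k log n, tau5 = HQIC = tau1 + 2k log log n,
tau6 = Cramér-von Mises W^2, tau7 = asymptotic one-sample Kolmogorov-Smirnov
p-value against the fitted cdf (no estimated-parameter correction), and
tau8 = Anderson-Darling A^2.  tau6 and tau8 are reported as statistics, not
p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .distribution import FrechetParams, NEFrParams, ObservationSet, frechet_cdf, frechet_logpdf, nefr_cdf
from .estimation import FitResult, ade_objective, cvm_statistic, loglik

__all__ = ["GofReport", "DescriptiveStats", "criteria", "descriptive", "ttt_curve"]


@dataclass(frozen=True)
class GofReport:
    tau1: float
    tau2: float
    tau3: Optional[float]
    tau4: float
    tau5: float
    tau6: float
    tau7: float
    tau8: float
    n: int
    k: int


@dataclass(frozen=True)
class DescriptiveStats:
    n: int
    mean: float
    median: float
    sd: float
    skewness: Optional[float]
    kurtosis: Optional[float]
    min: float
    max: float


def criteria(data: ObservationSet, fitted: FitResult) -> GofReport:
    """The tau1..tau8 criteria for a maximum-likelihood fit on a sample.

    Only likelihood-based fits are accepted (the information criteria are
    meaningless at a distance-estimator optimum).  AICc is reported as None
    when n <= k + 1.
    """
    if fitted.method != "mle":
        raise ValueError("criteria require a maximum-likelihood fit")
    n, k = data.n, fitted.k
    if isinstance(fitted.params, NEFrParams):
        ll = loglik(data, fitted.params)
        cdf = lambda z: nefr_cdf(z, fitted.params)
        w2 = cvm_statistic(data, fitted.params)
        a2 = ade_objective(data, fitted.params)
    else:
        q: FrechetParams = fitted.params
        ll = float(np.sum(frechet_logpdf(data.values, q)))
        cdf = lambda z: frechet_cdf(z, q)
        # reuse the NE_Fr machinery through the cdf values directly
        w2 = _cvm_from_cdf(data, cdf)
        a2 = _ad_from_cdf(data, cdf)
    tau1 = -2.0 * ll
    tau2 = tau1 + 2.0 * k
    tau3 = tau2 + 2.0 * k * (k + 1.0) / (n - k - 1.0) if n > k + 1 else None
    tau4 = tau1 + k * math.log(n)
    tau5 = tau1 + 2.0 * k * math.log(math.log(n))
    tau7 = float(stats.kstest(data.values, cdf, mode="asymp").pvalue)
    return GofReport(tau1, tau2, tau3, tau4, tau5, w2, tau7, a2, n=n, k=k)


def _cvm_from_cdf(data: ObservationSet, cdf) -> float:
    F = np.asarray(cdf(data.sorted_values), dtype=float)
    n = data.n
    i = np.arange(1, n + 1)
    return float(1.0 / (12.0 * n) + np.sum((F - (2.0 * i - 1.0) / (2.0 * n)) ** 2))


def _ad_from_cdf(data: ObservationSet, cdf) -> float:
    F = np.clip(np.asarray(cdf(data.sorted_values), dtype=float), 1e-300, 1 - 1e-16)
    n = data.n
    i = np.arange(1, n + 1)
    return float(-n - np.sum((2.0 * i - 1.0) * (np.log(F) + np.log1p(-F[::-1]))) / n)


def descriptive(data: ObservationSet) -> DescriptiveStats:
    """Sample descriptives: sd with the n-1 denominator; moment skewness
    m3/m2^(3/2) and excess kurtosis m4/m2^2 - 3, both with n-denominator
    central moments; both None for a constant sample."""
    z = data.values
    n = z.size
    if n < 2:
        raise ValueError("descriptive statistics need n >= 2")
    m = z.mean()
    c = z - m
    m2 = np.mean(c**2)
    sd = float(z.std(ddof=1))
    if m2 == 0.0:
        skew = kurt = None
    else:
        skew = float(np.mean(c**3) / m2**1.5)
        kurt = float(np.mean(c**4) / m2**2 - 3.0)
    return DescriptiveStats(
        n=n,
        mean=float(m),
        median=float(np.median(z)),
        sd=sd,
        skewness=skew,
        kurtosis=kurt,
        min=float(z.min()),
        max=float(z.max()),
    )


def ttt_curve(data: ObservationSet) -> tuple[np.ndarray, np.ndarray]:
    """Scaled total-time-on-test transform.

    Returns (i/n, T_i) for i = 0..n with
    T_i = [sum_{j<=i} z_(j) + (n-i) z_(i)] / sum_j z_(j), T_0 = 0, T_n = 1.
    A concave curve indicates increasing hazard, convex decreasing, and an
    S-shape a unimodal (upside-down) hazard.
    """
    zs = data.sorted_values
    n = zs.size
    if n < 2:
        raise ValueError("TTT transform needs n >= 2")
    csum = np.cumsum(zs)
    total = csum[-1]
    i = np.arange(1, n + 1)
    T = (csum + (n - i) * zs) / total
    return np.concatenate(([0.0], i / n)), np.concatenate(([0.0], T))
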