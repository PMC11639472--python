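"""The new extended Fréchet (NE_Fr) distribution.

The NE_Fr law is a three-parameter heavy-tailed lifetime model obtained by
passing the Fréchet (inverse Weibull) cdf ``G(z) = exp(-a z**-b)`` through a
ratio-type generator.  With parameters ``alpha > 0`` (scale-type),
``beta > 0`` (tail shape) and ``lam > 0`` (extra shape, with
``lam_bar = 1 - lam``), the cdf is

    F(z) = 1 - [(1 - e**(-2 a z**-b)) / (1 - lam_bar e**(-2 a z**-b))]**lam

For ``lam = 1`` the generator is the identity and the model collapses to a
Fréchet distribution with scale ``2*alpha`` and shape ``beta``.  The survival
function decays like ``(2 a / lam)**lam * z**(-b*lam)``, so the tail index is
``beta*lam`` and the r-th moment exists iff ``r < beta*lam``.

All functions are evaluated through log-scale identities (``expm1``/``log1p``)
so that they return finite values for ``z`` anywhere in ``[1e-12, 1e12]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

_LN2 = float(np.log(2.0))

__all__ = [
    "NEFrParams",
    "FrechetParams",
    "ObservationSet",
    "nefr_cdf",
    "nefr_logpdf",
    "nefr_pdf",
    "nefr_sf",
    "nefr_logsf",
    "nefr_hrf",
    "nefr_quantile",
    "nefr_rvs",
    "frechet_cdf",
    "frechet_pdf",
]


@dataclass(frozen=True)
class NEFrParams:
    """Parameter triple (alpha, beta, lam) of the NE_Fr distribution.

    ``lam_bar`` is derived storage, always equal to ``1 - lam``; it is never
    set independently.  ``lam = 1`` (``lam_bar = 0``) needs no special-casing
    anywhere: the same formulas reduce to the Fréchet(2*alpha, beta) ones.
    """

    alpha: float
    beta: float
    lam: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "lam"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be a positive finite real, got {v!r}")

    @property
    def lam_bar(self) -> float:
        return 1.0 - self.lam

    @property
    def tail_index(self) -> float:
        """Exponent of the power-law survival tail, ``beta * lam``."""
        return self.beta * self.lam

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.lam)


@dataclass(frozen=True)
class FrechetParams:
    """Scale/shape parameters of the baseline Fréchet (inverse Weibull) law."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be a positive finite real, got {v!r}")


@dataclass(frozen=True)
class ObservationSet:
    """An ordered sample of strictly positive durations with a provenance label."""

    values: np.ndarray
    label: str = ""
    _sorted: np.ndarray = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("ObservationSet needs a one-dimensional sample of length >= 1")
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            bad = int(np.argmax(~(np.isfinite(arr) & (arr > 0))))
            raise ValueError(
                f"all observations must be positive finite reals; "
                f"offending entry {arr[bad]!r} at index {bad}"
            )
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "_sorted", np.sort(arr))

    @classmethod
    def from_values(cls, values: Sequence[float], label: str = "") -> "ObservationSet":
        return cls(np.asarray(values, dtype=float), label)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def sorted_values(self) -> np.ndarray:
        """Stable ascending view z_(1) <= ... <= z_(n)."""
        return self._sorted


def _check_z(z):
    z = np.asarray(z, dtype=float)
    if np.any(~np.isfinite(z)) or np.any(z <= 0):
        raise ValueError("z must be strictly positive and finite")
    return z


def _w(z, p: NEFrParams):
    """Exponent w = 2*alpha*z**(-beta), computed in log space."""
    with np.errstate(over="ignore"):
        return np.exp(np.log(2.0 * p.alpha) - p.beta * np.log(z))


def _log1mexp(w):
    """log(1 - e**-w) for w > 0, accurate at both ends.

    Uses log(-expm1(-w)) for small w and log1p(-exp(-w)) for large w
    (crossover at w = log 2, where e**-w = 1/2)."""
    w = np.asarray(w, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        small = np.log(-np.expm1(-np.minimum(w, _LN2)))
        large = np.log1p(-np.exp(-np.maximum(w, _LN2)))
    return np.where(w < _LN2, small, large)


def _log_A_D(w, p: NEFrParams):
    """log(1 - e**-w) and log(1 - lam_bar*e**-w) without cancellation.

    The second factor is 1 + (lam-1) e**-w, evaluated through log1p so that
    it stays accurate when (lam-1) e**-w is tiny — the regime that matters on
    the flat large-lam likelihood ridge.
    """
    logA = _log1mexp(w)
    logD = np.log1p((p.lam - 1.0) * np.exp(-w))
    return logA, logD


def nefr_logsf(z, p: NEFrParams):
    """Log survival function, finite wherever the sf is positive."""
    z = _check_z(z)
    logA, logD = _log_A_D(_w(z, p), p)
    return p.lam * (logA - logD)


def nefr_sf(z, p: NEFrParams):
    """Survival function S(z) = [(1 - e**-w)/(1 - lam_bar e**-w)]**lam."""
    return np.exp(nefr_logsf(z, p))


def nefr_cdf(z, p: NEFrParams):
    """Distribution function of the NE_Fr law.

    Monotone nondecreasing in ``z`` with limits 0 at 0+ and 1 at infinity.
    Computed as ``-expm1(log sf)`` so that values near 1 keep full precision
    in ``1 - F``.
    """
    return -np.expm1(nefr_logsf(z, p))


def nefr_logpdf(z, p: NEFrParams):
    """Log density of the NE_Fr law; returns -inf where the density underflows."""
    z = _check_z(z)
    w = _w(z, p)
    logA, logD = _log_A_D(w, p)
    with np.errstate(divide="ignore"):
        return (
            np.log(2.0)
            + 2.0 * np.log(p.lam)
            + np.log(p.alpha)
            + np.log(p.beta)
            - (p.beta + 1.0) * np.log(z)
            - w
            + (p.lam - 1.0) * logA
            - (p.lam + 1.0) * logD
        )


def nefr_pdf(z, p: NEFrParams):
    """Density of the NE_Fr law (the analytic derivative of :func:`nefr_cdf`)."""
    return np.exp(nefr_logpdf(z, p))


def nefr_hrf(z, p: NEFrParams):
    """Hazard rate pdf/sf, computed on the log scale so it never returns NaN."""
    z = _check_z(z)
    return np.exp(nefr_logpdf(z, p) - nefr_logsf(z, p))


def nefr_quantile(prob, p: NEFrParams):
    """Closed-form quantile function.

    ``Q(u) = {-(1/(2 alpha)) * log[(1 - (1-u)**(1/lam)) /
    (1 - lam_bar (1-u)**(1/lam))]}**(-1/beta)`` for ``u`` in (0, 1).

    As ``u -> 1`` the quantile grows like ``(1-u)**(-1/(beta*lam))``; no
    clamping is applied.  Arguments 0 and 1 are rejected (they map to 0 and
    +inf only in the extended variant :func:`nefr_quantile_extended`).
    """
    prob = np.asarray(prob, dtype=float)
    if np.any(~np.isfinite(prob)) or np.any(prob <= 0.0) or np.any(prob >= 1.0):
        raise ValueError("prob must lie strictly inside (0, 1)")
    return _quantile_interior(prob, p)


def _quantile_interior(prob, p: NEFrParams):
    # u = (1-prob)**(1/lam); B = 1 - u via expm1/log1p keeps both ends exact
    lu = np.log1p(-prob) / p.lam
    u = np.exp(lu)
    B = -np.expm1(lu)  # 1 - u, accurate when u is near 1
    with np.errstate(divide="ignore"):
        # log B: through log1p(-u) when u is small (B near 1), log(B) otherwise
        logB = np.where(u < 0.5, np.log1p(-u), np.log(B))
    logD = np.log1p((p.lam - 1.0) * u)  # 1 - lam_bar*u
    w = logD - logB  # = -log E, the value of 2*alpha*z**-beta at the quantile
    return np.exp(-np.log(w / (2.0 * p.alpha)) / p.beta)


def nefr_quantile_extended(prob, p: NEFrParams):
    """Quantile with the boundary conventions Q(0) = 0 and Q(1) = +inf."""
    prob = np.asarray(prob, dtype=float)
    if np.any(~np.isfinite(prob)) or np.any(prob < 0.0) or np.any(prob > 1.0):
        raise ValueError("prob must lie in [0, 1]")
    out = np.empty_like(prob, dtype=float)
    lo, hi = prob == 0.0, prob == 1.0
    mid = ~(lo | hi)
    out[lo] = 0.0
    out[hi] = np.inf
    if np.any(mid):
        out[mid] = _quantile_interior(prob[mid], p)
    return out


def nefr_rvs(n: int, p: NEFrParams, seed, label: str = "nefr_rvs") -> ObservationSet:
    """Draw ``n`` i.i.d. NE_Fr variates by inverse-transform sampling.

    Deterministic for a fixed ``seed`` (a Python int or a ``numpy`` Generator).
    """
    if int(n) < 1:
        raise ValueError("n must be a positive integer")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random(int(n))
    # uniform() can return exactly 0.0; nudge into the open interval
    u = np.clip(u, np.finfo(float).tiny, 1.0 - np.finfo(float).epsneg)
    return ObservationSet(_quantile_interior(u, p), label)


# ---------------------------------------------------------------------------
# Baseline Fréchet (inverse Weibull)

def frechet_cdf(z, q: FrechetParams):
    """Fréchet cdf G(z) = exp(-alpha * z**-beta)."""
    z = _check_z(z)
    return np.exp(-np.exp(np.log(q.alpha) - q.beta * np.log(z)))


def frechet_logpdf(z, q: FrechetParams):
    z = _check_z(z)
    t = np.exp(np.log(q.alpha) - q.beta * np.log(z))
    return np.log(q.alpha) + np.log(q.beta) - (q.beta + 1.0) * np.log(z) - t


def frechet_pdf(z, q: FrechetParams):
    """Fréchet density g(z) = alpha*beta*z**(-beta-1)*exp(-alpha z**-beta)."""
    return np.exp(frechet_logpdf(z, q))
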