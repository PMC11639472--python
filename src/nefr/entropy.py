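"""Entropy measures of the NE_Fr distribution.

All four measures (Rényi, q/Tsallis, Havrda–Charvát, Arimoto) are monotone
transforms of the single integral ``I_rho = int f(z)**rho dz``:

    RE   = log(I_rho) / (1 - rho)
    QE   = (1 - I_rho) / (rho - 1)
    HaCE = (I_rho**(1/rho) - 1) / (2**(1-rho) - 1)
    ArE  = rho * (I_rho**(1/rho) - 1) / (1 - rho)

``I_rho`` is finite iff ``rho * (beta*lam + 1) > 1`` — the integrand decays
like ``z**(-rho (beta lam + 1))`` in the tail.  The series representation
carries the stronger requirement that its Gamma argument
``rho + (rho-1)/beta`` be positive (equivalently ``rho (beta+1) > 1``);
quadrature is the authoritative route.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import integrate, special

from .distribution import NEFrParams, nefr_logpdf, nefr_quantile
from .properties import NonexistenceError, SeriesControl, _sum_double_series

__all__ = ["EntropySpec", "integral_f_rho", "entropy", "shannon_entropy"]

Measure = Literal["renyi", "q", "havrda_charvat", "arimoto"]
_MEASURES = ("renyi", "q", "havrda_charvat", "arimoto")
_DEFAULT_CTRL = SeriesControl()


@dataclass(frozen=True)
class EntropySpec:
    """Order rho (> 0, != 1; tabulated in the field as epsilon) and measure name."""

    rho: float
    measure: Measure = "renyi"

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.rho == 1.0:
            raise ValueError("rho must be positive and different from 1")
        if self.measure not in _MEASURES:
            raise ValueError(f"measure must be one of {_MEASURES}")


def _check_quadrature_regime(rho: float, p: NEFrParams) -> None:
    if rho * (p.tail_index + 1.0) <= 1.0:
        raise NonexistenceError(
            "integral of f**rho diverges: need rho*(beta*lam + 1) > 1, "
            f"got rho={rho}, beta*lam={p.tail_index}"
        )


def integral_f_rho(
    rho: float,
    p: NEFrParams,
    method: Literal["series", "quadrature"] = "quadrature",
    ctrl: SeriesControl = _DEFAULT_CTRL,
) -> float:
    """The shared integral I_rho = int_0^inf f(z)**rho dz.

    Quadrature uses the substitution z = Q(u), giving
    ``int_0^1 f(Q(u))**(rho-1) du``.  The series sums
    ``Xi_{i,j} Gamma(rho + (rho-1)/beta) / (beta (2 alpha (rho+i+j))**(rho+(rho-1)/beta))``
    with ``Xi_{i,j} = (2 lam^2 alpha beta)**rho (-1)**j lam_bar**i
    binom(rho(lam+1)+i-1, i) binom(rho(lam-1), j)``.
    """
    if rho <= 0 or rho == 1.0:
        raise ValueError("rho must be positive and different from 1")
    _check_quadrature_regime(rho, p)
    if method == "series":
        a = rho + (rho - 1.0) / p.beta
        if a <= 0:
            raise NonexistenceError(
                "series Gamma argument rho + (rho-1)/beta must be positive "
                f"(i.e. rho*(beta+1) > 1), got {a}"
            )
        g = special.gamma(a)
        pref = (2.0 * p.lam**2 * p.alpha * p.beta) ** rho
        lb = p.lam_bar

        def a_fn(i: int) -> float:
            b1 = special.binom(rho * (p.lam + 1.0) + i - 1.0, i)
            return float(b1 * (lb**i if i > 0 else 1.0))

        def b_fn(j: int) -> float:
            return float(((-1.0) ** j) * special.binom(rho * (p.lam - 1.0), j))

        def kernel(s: int) -> float:
            c = 2.0 * p.alpha * (rho + s)
            return pref * c ** (-a) * g / p.beta

        return _sum_double_series(a_fn, b_fn, kernel, ctrl)

    def integrand(u):
        q = nefr_quantile(np.clip(u, 1e-315, 1 - 1e-16), p)
        return np.exp((rho - 1.0) * nefr_logpdf(q, p))

    val, _ = integrate.quad(integrand, 0.0, 1.0, limit=200)
    return val


def entropy(
    spec: EntropySpec,
    p: NEFrParams,
    method: Literal["series", "quadrature"] = "quadrature",
    ctrl: SeriesControl = _DEFAULT_CTRL,
) -> float:
    """One of the four entropy measures, computed from a single shared I_rho."""
    rho = spec.rho
    i_rho = integral_f_rho(rho, p, method, ctrl)
    if spec.measure == "renyi":
        return np.log(i_rho) / (1.0 - rho)
    if spec.measure == "q":
        return (1.0 - i_rho) / (rho - 1.0)
    if spec.measure == "havrda_charvat":
        return (i_rho ** (1.0 / rho) - 1.0) / (2.0 ** (1.0 - rho) - 1.0)
    return rho * (i_rho ** (1.0 / rho) - 1.0) / (1.0 - rho)  # arimoto


def shannon_entropy(p: NEFrParams) -> float:
    """Differential Shannon entropy -int f log f, the rho -> 1 limit of RE."""

    def integrand(u):
        q = nefr_quantile(np.clip(u, 1e-315, 1 - 1e-16), p)
        return -nefr_logpdf(q, p)

    val, _ = integrate.quad(integrand, 0.0, 1.0, limit=200)
    return val
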