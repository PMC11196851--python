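"""The inverse Lindley (IL) lifetime distribution.

If ``Y`` follows a Lindley distribution with scale ``theta``, then
``Z = 1/Y`` follows the inverse Lindley distribution.  With
``theta_bar = theta / (1 + theta)`` its density, distribution,
reliability and hazard functions are

    f(z) = theta * theta_bar * exp(-theta/z) * (1 + z) / z**3
    F(z) = (1 + theta_bar/z) * exp(-theta/z)
    R(z) = 1 - F(z)
    h(z) = f(z) / R(z)

for ``z > 0``.  The model has a single positive scale parameter and an
upside-down bathtub (unimodal) hazard, which makes it a convenient
parametric choice for repair-time and time-between-failure data.

All functions are vectorized over ``z`` and accept either a bare float
``theta`` or an :class:`ILParams`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

__all__ = [
    "ILParams",
    "ReliabilityQuery",
    "pdf",
    "logpdf",
    "cdf",
    "rf",
    "logrf",
    "hrf",
    "evaluate",
    "quantile",
    "quantile_lambertw",
    "sample",
]


@dataclass(frozen=True)
class ILParams:
    """Scale parameter of the inverse Lindley distribution.

    Attributes
    ----------
    theta : float
        Positive scale parameter (per unit time).
    """

    theta: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.theta) or self.theta <= 0:
            raise ValueError(f"theta must be a positive real, got {self.theta!r}")

    @property
    def theta_bar(self) -> float:
        """theta / (1 + theta), always in (0, 1)."""
        return self.theta / (1.0 + self.theta)

    @property
    def theta_bar_prime(self) -> float:
        """First derivative of theta_bar with respect to theta: 1/(1+theta)^2."""
        return 1.0 / (1.0 + self.theta) ** 2

    @property
    def theta_bar_dprime(self) -> float:
        """Second derivative of theta_bar: -2/(1+theta)^3."""
        return -2.0 / (1.0 + self.theta) ** 3


@dataclass(frozen=True)
class ReliabilityQuery:
    """A mission time ``t`` at which R(t) and h(t) are requested."""

    t: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.t) or self.t <= 0:
            raise ValueError(f"mission time t must be positive, got {self.t!r}")

    @property
    def sigma(self) -> float:
        """1 + t, a recurring factor in the delta-method gradients."""
        return 1.0 + self.t


def _theta_of(params) -> float:
    th = params.theta if isinstance(params, ILParams) else float(params)
    if not np.isfinite(th) or th <= 0:
        raise ValueError(f"theta must be a positive real, got {params!r}")
    return th


def _check_z(z) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0) or np.any(~np.isfinite(z)):
        raise ValueError("z must contain positive finite times only")
    return z


def logpdf(z, params) -> np.ndarray:
    """Log density; evaluated in log space so small z never underflows."""
    th = _theta_of(params)
    z = _check_z(z)
    return 2.0 * np.log(th) - np.log1p(th) - th / z + np.log1p(z) - 3.0 * np.log(z)


def pdf(z, params) -> np.ndarray:
    return np.exp(logpdf(z, params))


def cdf(z, params) -> np.ndarray:
    """F(z) = (1 + theta_bar/z) exp(-theta/z); 0 for z <= 0 in vectorized use."""
    th = _theta_of(params)
    z = np.asarray(z, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            z > 0,
            (1.0 + (th / (1.0 + th)) / np.maximum(z, np.finfo(float).tiny))
            * np.exp(-th / np.maximum(z, np.finfo(float).tiny)),
            0.0,
        )
    return out


def rf(z, params) -> np.ndarray:
    """Reliability (survival) function R(z) = 1 - F(z)."""
    return 1.0 - cdf(z, params)


def logrf(z, params) -> np.ndarray:
    """log R(z) computed as -theta/z + log(expm1(theta/z) - theta_bar/z).

    Writing R = exp(-theta*x) * (exp(theta*x) - 1 - theta_bar*x) with
    x = 1/z keeps full precision for large z, where 1 - F(z) would
    cancel catastrophically.
    """
    th = _theta_of(params)
    z = _check_z(z)
    x = np.atleast_1d(1.0 / z)
    tbar = th / (1.0 + th)
    s = th * x
    out = np.empty_like(x)
    small = s < 30.0
    out[small] = -s[small] + np.log(np.expm1(s[small]) - tbar * x[small])
    big = ~small  # factor e^{theta x} out before it overflows
    out[big] = np.log1p(-(1.0 + tbar * x[big]) * np.exp(-s[big]))
    return out if np.ndim(z) else out[0]


def hrf(z, params) -> np.ndarray:
    """Hazard rate h(z) = f(z)/R(z)."""
    return np.exp(logpdf(z, params) - logrf(z, params))


def evaluate(z, params) -> dict:
    """Evaluate pdf, cdf, reliability and hazard at ``z`` in one call."""
    return {
        "pdf": pdf(z, params),
        "cdf": cdf(z, params),
        "rf": rf(z, params),
        "hrf": hrf(z, params),
    }


def quantile(p, params) -> np.ndarray:
    """Inverse CDF by safeguarded root finding.

    Solved in the variable ``u = theta/z`` where the equation
    ``(1 + u/(1+theta)) e^{-u} = p`` is strictly decreasing, so a single
    bracket works for any p in (0, 1).  The Lambert-W closed form
    (:func:`quantile_lambertw`) is kept as an independent cross-check.
    """
    th = _theta_of(params)
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("p must lie strictly inside (0, 1)")

    def _solve(pi: float) -> float:
        f = lambda u: (1.0 + u / (1.0 + th)) * np.exp(-u) - pi
        lo, hi = 1e-12, 745.0  # exp(-745) is the smallest positive double
        u = optimize.brentq(f, lo, hi, xtol=1e-14, rtol=1e-15)
        return th / u

    out = np.vectorize(_solve, otypes=[float])(p)
    return out if out.ndim else float(out)


def quantile_lambertw(p, params) -> np.ndarray:
    """Closed-form inverse CDF via the secondary real Lambert-W branch.

    From ``(1 + theta + u) e^{-u} = p (1 + theta)`` with ``u = theta/z``,
    ``u = -(1+theta) - W_{-1}(-p (1+theta) e^{-(1+theta)})``.
    """
    th = _theta_of(params)
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("p must lie strictly inside (0, 1)")
    arg = -p * (1.0 + th) * np.exp(-(1.0 + th))
    u = -(1.0 + th) - special.lambertw(arg, k=-1).real
    out = th / u
    return out if out.ndim else float(out)


def sample(params, size: int, seed=None) -> np.ndarray:
    """i.i.d. draws by inverse transform; reproducible under a fixed seed."""
    if size < 1:
        raise ValueError("size must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random(size)
    # Clip away exact 0 (cdf limit); rng.random() never returns 1.0.
    u = np.clip(u, np.finfo(float).tiny, None)
    return np.asarray(quantile_lambertw(u, params), dtype=float)
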