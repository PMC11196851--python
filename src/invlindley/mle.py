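"""Likelihood inference for the inverse Lindley model under AT-IPC data.

The observed-data log-likelihood for failures ``z_1 < ... < z_k`` with
applied removals ``S_i`` and ``S*`` units withdrawn at ``tau`` is

    l(theta) = sum_i log f(z_i) + sum_i S_i log R(z_i) + S* log R(tau),

maximized by scalar bounded optimization with a Newton polish on the
analytic score.  The Wald variance is the negative inverse of the
analytic second derivative (observed information), and intervals for
R(t) and h(t) follow by the delta method with analytic gradients.

Note the log-likelihood here retains the theta-free data constant
``sum log((1+z_i)/z_i^3)`` so that reported maxima plug directly into
information criteria; the score and information are unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from . import il_model
from .censoring import ATIPCSample

__all__ = [
    "PointFit",
    "IntervalEstimate",
    "EstimationFailure",
    "loglik",
    "score",
    "loglik_second_derivative",
    "fit_mle",
    "wald_intervals",
    "rf_gradient",
    "hrf_gradient",
]

_THETA_BOUNDS = (1e-6, 1e3)


class EstimationFailure(RuntimeError):
    """Optimizer failed to locate a stationary interior maximum."""


@dataclass(frozen=True)
class IntervalEstimate:
    lower: float
    upper: float
    level: float
    method: str

    def __post_init__(self) -> None:
        if not (0 < self.level < 1):
            raise ValueError("level must be in (0, 1)")
        if self.lower > self.upper:
            raise ValueError("lower must not exceed upper")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass(frozen=True)
class PointFit:
    """A point estimate of theta with its Wald variance and plug-ins."""

    method: str
    theta_hat: float
    var_theta: float
    t: float | None = None
    rf_hat: float | None = None
    hrf_hat: float | None = None
    meta: dict = field(default_factory=dict, compare=False)

    @property
    def se(self) -> float:
        return float(np.sqrt(self.var_theta))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "theta_hat": self.theta_hat,
            "se": self.se,
            "t": self.t,
            "rf_hat": self.rf_hat,
            "hrf_hat": self.hrf_hat,
        }


def _censoring_terms(sample: ATIPCSample):
    """(x, S) pairs carrying a log-reliability factor, S* and T included."""
    xs = list(sample.x[sample.s_applied > 0])
    ws = list(sample.s_applied[sample.s_applied > 0].astype(float))
    if sample.s_star > 0:
        if sample.T <= 0:
            raise ValueError("S* > 0 requires a finite tau")
        xs.append(sample.T)
        ws.append(float(sample.s_star))
    return np.asarray(xs), np.asarray(ws)


_EXP_SWITCH = 30.0  # above this, e^{theta x} dominates and we factor it out


def _g(x, theta):
    """log(e^{theta x} - 1 - theta_bar x); log R = -theta x + g.

    Small theta*x uses expm1 (the difference is O((theta x)^2));
    large theta*x factors out e^{theta x} to avoid overflow.
    """
    x = np.asarray(x, dtype=float)
    tbar = theta / (1.0 + theta)
    s = theta * x
    small = s < _EXP_SWITCH
    out = np.empty_like(x)
    out[small] = np.log(np.expm1(s[small]) - tbar * x[small])
    big = ~small
    out[big] = s[big] + np.log1p(-(1.0 + tbar * x[big]) * np.exp(-s[big]))
    return out


def _g1(x, theta):
    """d/dtheta of _g: x (e^{theta x} - theta_bar') / (e^{theta x}-1-theta_bar x)."""
    x = np.asarray(x, dtype=float)
    tbar = theta / (1.0 + theta)
    tbp = 1.0 / (1.0 + theta) ** 2
    s = theta * x
    small = s < _EXP_SWITCH
    out = np.empty_like(x)
    den = np.expm1(s[small]) - tbar * x[small]
    out[small] = x[small] * (np.exp(s[small]) - tbp) / den
    big = ~small
    e = np.exp(-s[big])
    out[big] = x[big] * (1.0 - tbp * e) / (1.0 - (1.0 + tbar * x[big]) * e)
    return out


def _g2(x, theta):
    """Second theta-derivative of _g."""
    x = np.asarray(x, dtype=float)
    tbar = theta / (1.0 + theta)
    tbp = 1.0 / (1.0 + theta) ** 2
    tbpp = -2.0 / (1.0 + theta) ** 3
    s = theta * x
    small = s < _EXP_SWITCH
    out = np.empty_like(x)
    den = np.expm1(s[small]) - tbar * x[small]
    n1 = x[small] * (np.exp(s[small]) - tbp)
    n2 = x[small] * (x[small] * np.exp(s[small]) - tbpp)
    out[small] = n2 / den - (n1 / den) ** 2
    big = ~small
    e = np.exp(-s[big])
    denb = 1.0 - (1.0 + tbar * x[big]) * e
    g1b = x[big] * (1.0 - tbp * e) / denb
    n2b = x[big] * (x[big] - tbpp * e) / denb
    out[big] = n2b - g1b**2
    return out


def loglik(theta: float, sample: ATIPCSample) -> float:
    """Observed-data log-likelihood (full, including the data constant)."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    out = float(np.sum(il_model.logpdf(sample.z, theta)))
    x, w = _censoring_terms(sample)
    if x.size:
        out += float(np.sum(w * (-theta * x + _g(x, theta))))
    return out


def score(theta: float, sample: ATIPCSample) -> float:
    """Analytic first derivative of :func:`loglik` in theta."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    k = sample.k
    out = 2.0 * k / theta - k / (1.0 + theta) - float(np.sum(sample.x))
    x, w = _censoring_terms(sample)
    if x.size:
        out += float(np.sum(w * (-x + _g1(x, theta))))
    return out


def loglik_second_derivative(theta: float, sample: ATIPCSample) -> float:
    """Analytic second derivative of :func:`loglik` in theta."""
    k = sample.k
    out = -2.0 * k / theta**2 + k / (1.0 + theta) ** 2
    x, w = _censoring_terms(sample)
    if x.size:
        out += float(np.sum(w * _g2(x, theta)))
    return out


def _maximize(objective, d1, d2, init: float | None, label: str):
    """Bounded scalar maximization plus Newton polish on the gradient."""
    res = optimize.minimize_scalar(
        lambda th: -objective(th),
        bounds=_THETA_BOUNDS,
        method="bounded",
        options={"xatol": 1e-12},
    )
    theta = float(res.x)
    if init is not None and objective(init) > objective(theta):
        theta = float(init)
    for _ in range(60):
        g = d1(theta)
        h = d2(theta)
        if not np.isfinite(g) or not np.isfinite(h) or h >= 0:
            break
        if abs(g) <= 1e-9 * max(1.0, abs(h)):
            break
        cand = theta - g / h
        if not np.isfinite(cand) or cand <= 0:
            cand = theta / 2.0
        if not np.isfinite(d1(cand)) or abs(d1(cand)) >= abs(g):
            break
        theta = cand
    # gradient tolerance scales with the curvature of the objective
    if abs(d1(theta)) > 1e-6 * max(1.0, abs(d2(theta))):
        raise EstimationFailure(
            f"{label}: no interior stationary point found "
            f"(theta={theta:.6g}, gradient={d1(theta):.3g})"
        )
    curv = d2(theta)
    if curv >= 0:
        raise EstimationFailure(f"{label}: non-concave at optimum (d2={curv:.3g})")
    return theta, -1.0 / curv


def _moment_init(sample: ATIPCSample) -> float:
    # crude scale guess: reciprocal-time mean, clipped to the search box
    guess = sample.k / float(np.sum(sample.x))
    if not np.isfinite(guess) or guess <= 0:
        return 1.0
    return float(np.clip(guess, *_THETA_BOUNDS))


def fit_mle(sample: ATIPCSample, t: float | None = None, init: float | None = None) -> PointFit:
    """Maximum likelihood estimate of theta with observed-information variance.

    Parameters
    ----------
    sample : ATIPCSample
    t : optional mission time; when given, R(t) and h(t) plug-ins are filled.
    init : optional starting value (defaults to a moment-style guess).
    """
    start = init if init is not None else _moment_init(sample)
    theta, var = _maximize(
        lambda th: loglik(th, sample),
        lambda th: score(th, sample),
        lambda th: loglik_second_derivative(th, sample),
        start,
        "MLE",
    )
    rf_hat = float(il_model.rf(t, theta)) if t is not None else None
    hrf_hat = float(il_model.hrf(t, theta)) if t is not None else None
    return PointFit(
        method="MLE",
        theta_hat=theta,
        var_theta=var,
        t=t,
        rf_hat=rf_hat,
        hrf_hat=hrf_hat,
        meta={"loglik": loglik(theta, sample)},
    )


def rf_gradient(t: float, theta: float) -> float:
    """dR(t)/dtheta, used by the delta method."""
    u = 1.0 / t
    tbar = theta / (1.0 + theta)
    tbp = 1.0 / (1.0 + theta) ** 2
    return u * np.exp(-theta * u) * (1.0 + tbar * u - tbp)


def hrf_gradient(t: float, theta: float) -> float:
    """dh(t)/dtheta, used by the delta method."""
    u = 1.0 / t
    f = float(il_model.pdf(t, theta))
    R = float(il_model.rf(t, theta))
    df = f * (2.0 / theta - 1.0 / (1.0 + theta) - u)
    dR = rf_gradient(t, theta)
    return (df * R - f * dR) / R**2


def wald_intervals(fit: PointFit, t: float, level: float = 0.95) -> dict:
    """Wald interval for theta and delta-method intervals for R(t), h(t).

    Bounds are reported unclipped, exactly as the asymptotic recipe
    produces them (a lower bound may fall below zero).
    """
    if fit.var_theta <= 0:
        raise ValueError("degenerate information: var_theta must be positive")
    zq = stats.norm.ppf(0.5 + level / 2.0)
    th, se = fit.theta_hat, fit.se
    label = fit.method
    out = {
        "theta": IntervalEstimate(th - zq * se, th + zq * se, level, label),
        "rf": None,
        "hrf": None,
    }
    se_rf = abs(rf_gradient(t, th)) * se
    se_hrf = abs(hrf_gradient(t, th)) * se
    rf_hat = float(il_model.rf(t, th))
    hrf_hat = float(il_model.hrf(t, th))
    out["rf"] = IntervalEstimate(rf_hat - zq * se_rf, rf_hat + zq * se_rf, level, label)
    out["hrf"] = IntervalEstimate(hrf_hat - zq * se_hrf, hrf_hat + zq * se_hrf, level, label)
    return out
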