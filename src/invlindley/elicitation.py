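"""Gamma-prior hyperparameter elicitation from pilot samples.

Simulate G complete samples of size n from IL(theta_true), estimate
theta on each (MLE or MPSE), and match the gamma prior's mean and
variance to the sample mean and (G-1)-denominator sample variance of
those estimates:

    a = mean^2 / var,    b = mean / var,

so that a/b equals the sample mean exactly and Gamma(a, b) has exactly
the empirical first two moments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import il_model
from .censoring import complete_sample
from .mle import fit_mle
from .mps import fit_mpse

__all__ = ["ElicitationResult", "elicit", "elicit_from_estimates"]


@dataclass(frozen=True)
class ElicitationResult:
    a_breve: float
    b_breve: float
    G: int
    estimator: str
    mean_estimate: float
    var_estimate: float


def elicit_from_estimates(estimates, estimator: str = "MLE") -> ElicitationResult:
    """Moment-match a gamma prior to an existing vector of estimates."""
    est = np.asarray(estimates, dtype=float)
    if est.size < 2:
        raise ValueError("need at least two estimates")
    mean = float(est.mean())
    var = float(est.var(ddof=1))
    if var <= 0:
        raise ValueError("degenerate elicitation: zero sample variance")
    return ElicitationResult(
        a_breve=mean**2 / var,
        b_breve=mean / var,
        G=int(est.size),
        estimator=estimator,
        mean_estimate=mean,
        var_estimate=var,
    )


def elicit(theta_true: float, n: int, G: int, estimator: str = "MLE",
           seed=None) -> ElicitationResult:
    """Elicit (a, b) from G simulated complete pilot samples of size n."""
    if G < 2:
        raise ValueError("G must be >= 2")
    if n < 2:
        raise ValueError("n must be >= 2")
    if estimator not in ("MLE", "MPSE"):
        raise ValueError("estimator must be 'MLE' or 'MPSE'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fit = fit_mle if estimator == "MLE" else fit_mpse
    estimates = np.empty(G)
    for i in range(G):
        data = il_model.sample(theta_true, n, rng)
        estimates[i] = fit(complete_sample(data)).theta_hat
    return elicit_from_estimates(estimates, estimator)
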