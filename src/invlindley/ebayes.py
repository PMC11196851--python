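"""E-Bayesian estimation: averaging the Bayes estimator over a hyperprior.

The gamma prior's hyperparameters (a, b) are themselves random:
``a ~ Beta(eps1, eps2)`` on (0,1) and ``b ~ Uniform(0, c)``,
independent.  The E-Bayes point estimate of a functional ϖ(theta) is
the expectation of the ordinary Bayes estimate over that hyperprior,
evaluated by Monte Carlo: draw J hyperparameter pairs, run one M-H
chain per pair, and average the J posterior means.  The E-BCI is the
equal-tailed percentile interval of the draws pooled across all J
chains (a sample from the hyperprior-mixed marginal posterior).

Beta draws keep ``a`` below 1, which is the regime in which the gamma
prior is decreasing in theta; elicited shapes ``a >= 1`` are legal as
plain Bayes priors but trigger a warning if used here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .bayes import Estimand, IntervalEstimate, MCMCChain, PriorSpec, mh_sample
from .censoring import ATIPCSample
from .mle import fit_mle
from .mps import SpacingConfig, fit_mpse

__all__ = ["HyperPriorSpec", "EBayesResult", "sample_hyperprior", "fit_ebayes"]


@dataclass(frozen=True)
class HyperPriorSpec:
    """Beta(eps1, eps2) prior on the gamma shape a; Uniform(0, c) on the rate b."""

    eps1: float = 0.75
    eps2: float = 0.75
    c: float = 1.0

    def __post_init__(self) -> None:
        if self.eps1 <= 0 or self.eps2 <= 0:
            raise ValueError("beta shapes eps1, eps2 must be positive")
        if self.c <= 0:
            raise ValueError("uniform upper bound c must be positive")


@dataclass(frozen=True)
class EBayesResult:
    method: str
    points: dict            # estimand name -> E-Bayes point
    intervals: dict         # estimand name -> IntervalEstimate (pooled draws)
    per_draw_points: dict   # estimand name -> array of J per-(a_j,b_j) Bayes points
    hyper_draws: np.ndarray  # (J, 2) array of (a_j, b_j)
    n_failed: int = 0
    meta: dict = field(default_factory=dict, compare=False)


def sample_hyperprior(hyper: HyperPriorSpec, J: int, seed=None) -> np.ndarray:
    """J i.i.d. (a, b) pairs from the Beta x Uniform hyperprior."""
    if J < 1:
        raise ValueError("J must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = rng.beta(hyper.eps1, hyper.eps2, size=J)
    b = rng.uniform(0.0, hyper.c, size=J)
    if np.any(a >= 1.0):
        warnings.warn("hyperprior draw a >= 1: gamma prior no longer decreasing")
    return np.column_stack([a, b])


def fit_ebayes(sample: ATIPCSample, hyper: HyperPriorSpec, source: str = "LF",
               estimands: list | None = None, J: int = 100,
               n_iter: int = 2_500, burn_in: int = 500,
               level: float = 0.95, seed=None,
               config: SpacingConfig | None = None,
               min_success: float = 0.9,
               proposal_scale: float = 0.25) -> EBayesResult:
    """Monte-Carlo E-Bayes estimation over the (a, b) hyperprior.

    One M-H chain per hyperprior draw; the frequentist initializer (MLE
    for LF, MPSE for SF) is fitted once and shared across chains.  A
    failing inner chain is skipped and counted; more than
    ``(1 - min_success) * J`` failures aborts.
    """
    estimands = estimands or [Estimand("theta")]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hyper_draws = sample_hyperprior(hyper, J, rng)
    start = fit_mle(sample) if source == "LF" else fit_mpse(sample, config=config)
    names = [e.which if e.which == "theta" else f"{e.which}({e.t:g})" for e in estimands]
    per_draw: dict = {nm: [] for nm in names}
    pooled: list[np.ndarray] = []
    n_failed = 0
    acc_rates = []
    for a_j, b_j in hyper_draws:
        try:
            chain = mh_sample(
                sample,
                PriorSpec(a=a_j, b=b_j),
                source=source,
                n_iter=n_iter,
                burn_in=burn_in,
                seed=rng,
                config=config,
                init=start.theta_hat,
                proposal_sd=proposal_scale * start.se,
            )
        except (ValueError, RuntimeError):
            n_failed += 1
            continue
        pooled.append(chain.draws)
        acc_rates.append(chain.acceptance_rate)
        for nm, est in zip(names, estimands):
            per_draw[nm].append(float(np.mean(est.transform(chain.draws))))
    if J - n_failed < min_success * J:
        raise RuntimeError(
            f"too many inner-chain failures: {n_failed}/{J} "
            f"(minimum success fraction {min_success})"
        )
    pooled_draws = np.concatenate(pooled)
    method = f"E-Bayes-{source}"
    points, intervals, per_draw_arr = {}, {}, {}
    for nm, est in zip(names, estimands):
        arr = np.asarray(per_draw[nm])
        per_draw_arr[nm] = arr
        points[nm] = float(arr.mean())
        vals = est.transform(pooled_draws)
        lo, hi = np.quantile(vals, [(1 - level) / 2.0, (1 + level) / 2.0])
        intervals[nm] = IntervalEstimate(float(lo), float(hi), level, method)
    return EBayesResult(
        method=method,
        points=points,
        intervals=intervals,
        per_draw_points=per_draw_arr,
        hyper_draws=hyper_draws,
        n_failed=n_failed,
        meta={
            "eps1": hyper.eps1,
            "eps2": hyper.eps2,
            "c": hyper.c,
            "J": J,
            "n_iter": n_iter,
            "burn_in": burn_in,
            "mean_acceptance_rate": float(np.mean(acc_rates)) if acc_rates else np.nan,
        },
    )
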