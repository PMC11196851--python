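"""Monte-Carlo evaluation harness and goodness-of-fit utilities.

``run_scenario`` repeats: simulate an adaptively censored sample, fit
the requested estimators, and aggregate

    Av.E  = mean of the estimates,
    RMSE  = root mean squared error about the true value,
    MAB   = mean absolute bias,
    ACL   = mean interval width (and empirical coverage as a bonus),

with the replicate count in the denominators.  Replicate r draws its
RNG from a child seed spawned deterministically from (master seed, r),
so results are independent of execution order.

Two generation mechanisms are available (see the censoring module):
``"fixed_k"`` observes exactly k = m failures with removals suspended
after tau — the convention under which published design tables that fix
an effective sample size per test are reproducible — and ``"atipc"``,
the sequential time-truncated mechanism under which k is random; the
report carries realized-k summaries so the difference stays visible.

``ks_gof`` and ``information_criteria`` serve the complete-data model
checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from . import il_model
from .bayes import Estimand, PriorSpec, mh_sample, summarize
from .censoring import (
    ATIPCSample,
    CensoringPlan,
    DegenerateSampleError,
    simulate_atipc,
    simulate_fixed_k,
)
from .ebayes import HyperPriorSpec, fit_ebayes
from .mle import EstimationFailure, fit_mle, wald_intervals
from .mps import SpacingConfig, fit_mpse, wald_intervals_sf

__all__ = [
    "Scenario",
    "SimulationReport",
    "run_scenario",
    "summary_metrics",
    "ks_gof",
    "information_criteria",
]


def summary_metrics(estimates, true_value: float, widths=None, cover=None) -> dict:
    """Av.E, RMSE and MAB of a vector of estimates (ACL/coverage optional).

    Denominators use the replicate count actually supplied.
    """
    pts = np.asarray(estimates, dtype=float)
    if pts.size == 0:
        raise ValueError("no estimates to aggregate")
    err = pts - true_value
    rmse = float(np.sqrt(np.mean(err**2)))
    out = {
        "AvE": float(pts.mean()),
        "RMSE": rmse,
        "MAB": float(np.mean(np.abs(err))),
        "mc_se": rmse / np.sqrt(pts.size),
    }
    out["ACL"] = float(np.mean(widths)) if widths is not None else np.nan
    out["coverage"] = float(np.mean(cover)) if cover is not None else np.nan
    return out


@dataclass(frozen=True)
class Scenario:
    """One simulation design: censoring plan, truth, methods, replicates."""

    n: int
    scheme: tuple
    tau: float
    theta_true: float
    label: str = ""
    t: float = 0.1
    methods: tuple = ("MLE", "MPSE")
    reps: int = 1000
    level: float = 0.95
    mechanism: str = "fixed_k"  # or "atipc"
    m: int | None = None  # defaults to len(scheme) under fixed_k
    prior: PriorSpec = field(default_factory=PriorSpec)
    hyper: HyperPriorSpec = field(default_factory=HyperPriorSpec)
    mcmc: dict = field(default_factory=lambda: {"n_iter": 10_000, "burn_in": 2_000})
    ebayes: dict = field(default_factory=lambda: {"J": 100, "n_iter": 2_500, "burn_in": 500})

    def plan(self) -> CensoringPlan:
        m = self.m if self.m is not None else len(self.scheme)
        # removals beyond position m-1 can never be applied; fold them out
        return CensoringPlan(n=self.n, m=m, scheme=tuple(self.scheme)[: m - 1], tau=self.tau)


@dataclass(frozen=True)
class SimulationReport:
    scenario: Scenario
    table: pd.DataFrame          # columns: method, estimand, AvE, RMSE, MAB, ACL, coverage, mc_se
    n_reps_used: int
    n_failed: int
    realized_k: np.ndarray

    def to_csv(self, path) -> None:
        df = self.table.copy()
        df.insert(0, "n", self.scenario.n)
        df.insert(1, "test", self.scenario.label)
        df.insert(2, "tau", self.scenario.tau)
        df["reps"] = self.n_reps_used
        df.to_csv(path, index=False)


def _true_values(scn: Scenario) -> dict:
    th = scn.theta_true
    return {
        "theta": th,
        "rf": float(il_model.rf(scn.t, th)),
        "hrf": float(il_model.hrf(scn.t, th)),
    }


def _fit_one(method: str, sample: ATIPCSample, scn: Scenario, rng) -> dict:
    """Return {estimand: (point, interval)} for one method on one sample."""
    t, level = scn.t, scn.level
    cfg = SpacingConfig()
    if method == "MLE":
        fit = fit_mle(sample, t=t)
        ints = wald_intervals(fit, t, level)
        return {
            "theta": (fit.theta_hat, ints["theta"]),
            "rf": (fit.rf_hat, ints["rf"]),
            "hrf": (fit.hrf_hat, ints["hrf"]),
        }
    if method == "MPSE":
        fit = fit_mpse(sample, t=t, config=cfg)
        ints = wald_intervals_sf(fit, t, level)
        return {
            "theta": (fit.theta_hat, ints["theta"]),
            "rf": (fit.rf_hat, ints["rf"]),
            "hrf": (fit.hrf_hat, ints["hrf"]),
        }
    if method in ("Bayes-LF", "Bayes-SF"):
        source = method[-2:]
        chain = mh_sample(sample, scn.prior, source=source, seed=rng,
                          config=cfg, **scn.mcmc)
        out = {}
        for name in ("theta", "rf", "hrf"):
            est = Estimand(name, None if name == "theta" else t)
            out[name] = summarize(chain, est, level)
        return out
    if method in ("E-Bayes-LF", "E-Bayes-SF"):
        source = method[-2:]
        ests = [Estimand("theta"), Estimand("rf", t), Estimand("hrf", t)]
        res = fit_ebayes(sample, scn.hyper, source=source, estimands=ests,
                         level=level, seed=rng, config=cfg, **scn.ebayes)
        key = {"theta": "theta", "rf": f"rf({t:g})", "hrf": f"hrf({t:g})"}
        return {nm: (res.points[key[nm]], res.intervals[key[nm]]) for nm in key}
    raise ValueError(f"unknown method {method!r}")


def run_scenario(scn: Scenario, seed=None, max_failure_frac: float = 0.05) -> SimulationReport:
    """Run one full Monte-Carlo design and aggregate the accuracy metrics."""
    if scn.reps < 1:
        raise ValueError("reps must be >= 1")
    plan = scn.plan()
    truth = _true_values(scn)
    simulate = simulate_fixed_k if scn.mechanism == "fixed_k" else simulate_atipc
    master = np.random.SeedSequence(seed)
    child_seeds = master.spawn(scn.reps)
    records: dict = {(m, e): {"pts": [], "widths": [], "cover": []}
                     for m in scn.methods for e in ("theta", "rf", "hrf")}
    ks = []
    n_failed = 0
    for r in range(scn.reps):
        rng = np.random.default_rng(child_seeds[r])
        try:
            sample = simulate(plan, scn.theta_true, rng)
            fits = {m: _fit_one(m, sample, scn, rng) for m in scn.methods}
        except (DegenerateSampleError, EstimationFailure, ValueError, RuntimeError):
            n_failed += 1
            if n_failed > max_failure_frac * scn.reps:
                raise RuntimeError(
                    f"more than {max_failure_frac:.0%} of replicates failed"
                )
            continue
        ks.append(sample.k)
        for m in scn.methods:
            for e in ("theta", "rf", "hrf"):
                point, interval = fits[m][e]
                rec = records[(m, e)]
                rec["pts"].append(point)
                rec["widths"].append(interval.width)
                rec["cover"].append(interval.contains(truth[e]))
    used = scn.reps - n_failed
    rows = []
    for (m, e), rec in records.items():
        metrics = summary_metrics(rec["pts"], truth[e], rec["widths"], rec["cover"])
        rows.append({"method": m, "estimand": e, "true": truth[e], **metrics})
    return SimulationReport(
        scenario=scn,
        table=pd.DataFrame(rows),
        n_reps_used=used,
        n_failed=n_failed,
        realized_k=np.asarray(ks),
    )


def ks_gof(data, theta_hat: float) -> dict:
    """Kolmogorov-Smirnov test of a complete sample against IL(theta_hat).

    D is the usual sup distance over the order statistics; the p-value
    uses the asymptotic Kolmogorov series 2 sum (-1)^{j-1} e^{-2 j^2 n D^2}.
    """
    z = np.sort(np.asarray(data, dtype=float))
    n = z.size
    if n == 0:
        raise ValueError("empty data")
    F = np.asarray(il_model.cdf(z, theta_hat))
    i = np.arange(1, n + 1)
    D = float(max(np.max(i / n - F), np.max(F - (i - 1) / n)))
    p = float(special.kolmogorov(np.sqrt(n) * D))
    return {"statistic": D, "p_value": p}


def information_criteria(loglik_max: float, p: int, n: int) -> dict:
    """Akaike, Bayesian, consistent-Akaike and Hannan-Quinn criteria."""
    if n <= p + 1:
        raise ValueError("consistent AIC undefined for n <= p + 1")
    A = -2.0 * loglik_max + 2.0 * p
    return {
        "A": A,
        "B": -2.0 * loglik_max + p * np.log(n),
        "CA": A + 2.0 * p * (p + 1) / (n - p - 1),
        "HQ": -2.0 * loglik_max + 2.0 * p * np.log(np.log(n)),
    }
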