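"""Adaptive Type-I progressively censored (AT-IPC) samples.

The life test puts ``n`` units on test with a removal plan
``S = (S_1, ..., S_{m-1})`` and a hard termination time ``tau``:

* at the i-th observed failure, for i <= m-1, ``S_i`` surviving units are
  withdrawn from the test;
* after the (m-1)-th failure no further planned withdrawals occur and the
  test keeps observing failures;
* the test always stops at ``tau``, at which point the ``S*`` units still
  at risk are withdrawn, so ``S* = n - k - sum_{i <= min(k, m-1)} S_i``
  where ``k`` is the number of observed failures.

This module validates observed samples against a plan, simulates them
(sequentially, plus a brute-force latent-lifetime oracle and a fixed-k
variant used by the simulation harness), and reads/writes the CSV + JSON
on-disk representation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import il_model

__all__ = [
    "CensoringPlan",
    "ATIPCSample",
    "from_observations",
    "complete_sample",
    "simulate_atipc",
    "simulate_latent",
    "simulate_fixed_k",
    "DegenerateSampleError",
    "write_sample",
    "read_sample",
]


class DegenerateSampleError(RuntimeError):
    """Raised when a simulated test terminates before the first failure."""


@dataclass(frozen=True)
class CensoringPlan:
    """A feasible AT-IPC design: (n, m, removal scheme, tau).

    ``scheme`` holds the planned removals S_1..S_{m-1}; a longer vector
    with trailing zeros is accepted.  ``tau = inf`` encodes a complete
    sample (no termination, no removals possible only if scheme is zero).
    """

    n: int
    m: int
    scheme: tuple = ()
    tau: float = np.inf

    def __post_init__(self) -> None:
        if not (1 <= self.m <= self.n):
            raise ValueError(f"need 1 <= m <= n, got m={self.m}, n={self.n}")
        sch = tuple(int(s) for s in self.scheme)
        if any(s < 0 for s in sch):
            raise ValueError("removal counts must be nonnegative")
        if len(sch) > self.m - 1 and any(s != 0 for s in sch[self.m - 1 :]):
            raise ValueError(
                "scheme entries beyond position m-1 must be zero "
                "(removals stop after the (m-1)-th failure)"
            )
        object.__setattr__(self, "scheme", sch)
        if sum(self.active_scheme) > self.n - self.m:
            raise ValueError("scheme removes more units than n - m allows")
        if not self.tau > 0:
            raise ValueError("tau must be positive (inf allowed)")

    @property
    def active_scheme(self) -> tuple:
        """Removals actually eligible to be applied: positions 1..m-1."""
        sch = self.scheme[: self.m - 1]
        return sch + (0,) * (self.m - 1 - len(sch))


@dataclass(frozen=True)
class ATIPCSample:
    """An observed AT-IPC dataset together with its censoring algebra."""

    z: np.ndarray
    s_applied: np.ndarray
    s_star: int
    tau: float
    n: int
    m: int
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        s = np.asarray(self.s_applied, dtype=int)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "s_applied", s)
        if z.ndim != 1 or z.size < 1:
            raise ValueError("need at least one observed failure (k >= 1)")
        if np.any(np.diff(z) < 0):
            raise ValueError("failure times must be sorted")
        if np.any(z <= 0):
            raise ValueError("failure times must be positive")
        if np.isfinite(self.tau) and z[-1] > self.tau:
            raise ValueError("observed failures must not exceed tau")
        if s.shape != z.shape:
            raise ValueError("s_applied must have one entry per failure")
        if self.s_star < 0:
            raise ValueError("S* must be nonnegative")
        if self.n != self.k + int(s.sum()) + self.s_star:
            raise ValueError(
                f"accounting identity violated: n={self.n} != "
                f"k={self.k} + removed={int(s.sum())} + S*={self.s_star}"
            )

    @property
    def k(self) -> int:
        return int(self.z.size)

    @property
    def x(self) -> np.ndarray:
        """Reciprocal failure times x_i = 1/z_i."""
        return 1.0 / self.z

    @property
    def T(self) -> float:
        """Reciprocal threshold 1/tau (0 for a complete sample)."""
        return 0.0 if np.isinf(self.tau) else 1.0 / self.tau

    @property
    def Q(self) -> float:
        """sum (1+S_i) x_i + S* T, the coefficient of -theta in the log-LF."""
        return float(np.sum((1.0 + self.s_applied) * self.x) + self.s_star * self.T)

    @property
    def Q_star(self) -> float:
        """sum S_i x_i + S* T, the spacing-function analogue of Q."""
        return float(np.sum(self.s_applied * self.x) + self.s_star * self.T)

    @property
    def is_complete(self) -> bool:
        return int(self.s_applied.sum()) == 0 and self.s_star == 0


def from_observations(times, plan: CensoringPlan) -> ATIPCSample:
    """Validate observed failure times against a plan and fill in S*.

    Removals follow the scheme at the first ``min(k, m-1)`` failures and
    are zero afterwards; whatever is left at ``tau`` becomes S*.
    """
    z = np.asarray(times, dtype=float)
    if z.size == 0:
        raise ValueError("k = 0 is unsupported: the likelihood needs k >= 1")
    k = z.size
    active = plan.active_scheme
    s_applied = np.zeros(k, dtype=int)
    upto = min(k, plan.m - 1)
    s_applied[:upto] = active[:upto]
    s_star = plan.n - k - int(s_applied.sum())
    if s_star < 0:
        raise ValueError(
            f"inconsistent plan: n={plan.n}, k={k}, "
            f"applied removals={int(s_applied.sum())} imply S*={s_star} < 0"
        )
    return ATIPCSample(
        z=z, s_applied=s_applied, s_star=s_star, tau=plan.tau, n=plan.n, m=plan.m
    )


def complete_sample(times) -> ATIPCSample:
    """Wrap a complete (uncensored) sample as the degenerate AT-IPC case."""
    z = np.sort(np.asarray(times, dtype=float))
    n = z.size
    return from_observations(z, CensoringPlan(n=n, m=n, scheme=(), tau=np.inf))


def _next_failure(t: float, r: int, theta: float, rng) -> float:
    """Draw the next order statistic given r units alive beyond time t."""
    u = rng.random()
    Ft = float(il_model.cdf(t, theta)) if t > 0 else 0.0
    p = 1.0 - (1.0 - Ft) * u ** (1.0 / r)
    p = min(max(p, np.finfo(float).tiny), 1.0 - 1e-16)
    return float(il_model.quantile_lambertw(p, theta))


def simulate_atipc(plan: CensoringPlan, params, seed=None) -> ATIPCSample:
    """Simulate one AT-IPC sample by sequential conditional generation.

    With ``r`` units at risk beyond time ``t``, the next failure is the
    conditional quantile ``F^{-1}(1 - (1-F(t)) U^{1/r})``.  Generation
    stops at the first candidate failure beyond ``tau`` (or when the risk
    set empties); removals follow the plan at the first m-1 failures.

    Raises
    ------
    DegenerateSampleError
        If the first failure falls beyond ``tau`` (k = 0); callers in the
        Monte-Carlo harness redraw and count the event.
    """
    theta = params.theta if isinstance(params, il_model.ILParams) else float(params)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    active = plan.active_scheme
    at_risk = plan.n
    t = 0.0
    zs: list[float] = []
    s_applied: list[int] = []
    truncated = False
    while at_risk > 0:
        znext = _next_failure(t, at_risk, theta, rng)
        if znext > plan.tau:
            break
        zs.append(znext)
        at_risk -= 1
        i = len(zs)
        want = active[i - 1] if i <= plan.m - 1 else 0
        r = min(want, at_risk)
        truncated = truncated or (r < want)
        s_applied.append(r)
        at_risk -= r
        t = znext
    if not zs:
        raise DegenerateSampleError(
            f"first failure beyond tau={plan.tau}; no observed failures"
        )
    meta = {"truncated_removals": truncated}
    return ATIPCSample(
        z=np.asarray(zs),
        s_applied=np.asarray(s_applied, dtype=int),
        s_star=at_risk,
        tau=plan.tau,
        n=plan.n,
        m=plan.m,
        meta=meta,
    )


def simulate_latent(plan: CensoringPlan, params, seed=None) -> ATIPCSample:
    """Brute-force oracle: simulate all n latent lifetimes, then apply the
    removal/termination bookkeeping directly.

    Slower than :func:`simulate_atipc` but mechanically transparent; the
    two generators agree in distribution and serve as mutual checks.
    """
    theta = params.theta if isinstance(params, il_model.ILParams) else float(params)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    alive = sorted(il_model.sample(theta, plan.n, rng).tolist())
    active = plan.active_scheme
    zs: list[float] = []
    s_applied: list[int] = []
    while alive:
        znext = alive[0]
        if znext > plan.tau:
            break
        alive.pop(0)
        zs.append(znext)
        i = len(zs)
        want = active[i - 1] if i <= plan.m - 1 else 0
        r = min(want, len(alive))
        # removal is uniformly at random among survivors
        for idx in sorted(rng.choice(len(alive), size=r, replace=False), reverse=True):
            alive.pop(idx)
        s_applied.append(r)
    if not zs:
        raise DegenerateSampleError("first failure beyond tau")
    return ATIPCSample(
        z=np.asarray(zs),
        s_applied=np.asarray(s_applied, dtype=int),
        s_star=len(alive),
        tau=plan.tau,
        n=plan.n,
        m=plan.m,
    )


def simulate_fixed_k(plan: CensoringPlan, params, seed=None) -> ATIPCSample:
    """Simulate with the number of failures fixed at k = m.

    This is the convention under which Monte-Carlo designs that state an
    "effective censored-sample size" are reproducible: the test always
    observes exactly ``m`` failures, planned removals are applied only at
    failures occurring at or before ``tau`` (the adaptive rule suspends
    withdrawals after the threshold), and every unit still at risk is
    withdrawn at the final failure.  The final withdrawal is recorded as
    a right-censoring at ``z_k`` via ``tau = z_k`` so that the standard
    AT-IPC likelihood applies unchanged.
    """
    theta = params.theta if isinstance(params, il_model.ILParams) else float(params)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    active = plan.active_scheme
    at_risk = plan.n
    t = 0.0
    zs: list[float] = []
    s_applied: list[int] = []
    for i in range(1, plan.m + 1):
        znext = _next_failure(t, at_risk, theta, rng)
        zs.append(znext)
        at_risk -= 1
        if i <= plan.m - 1:
            want = active[i - 1] if znext <= plan.tau else 0
            # never remove so many that m failures become unreachable
            r = min(want, at_risk - (plan.m - i))
            s_applied.append(r)
            at_risk -= r
        t = znext
    s_applied.append(0)
    return ATIPCSample(
        z=np.asarray(zs),
        s_applied=np.asarray(s_applied, dtype=int),
        s_star=at_risk,
        tau=zs[-1],
        n=plan.n,
        m=plan.m,
        meta={"mechanism": "fixed_k", "design_tau": plan.tau},
    )


def write_sample(sample: ATIPCSample, csv_path) -> None:
    """Write ``time,removed`` rows plus a JSON sidecar with the plan."""
    csv_path = Path(csv_path)
    df = pd.DataFrame({"time": sample.z, "removed": sample.s_applied})
    df.to_csv(csv_path, index=False)
    sidecar = {
        "n": int(sample.n),
        "m": int(sample.m),
        "tau": None if np.isinf(sample.tau) else float(sample.tau),
        "s_star": int(sample.s_star),
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_sample(csv_path) -> ATIPCSample:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    side = json.loads(csv_path.with_suffix(".json").read_text())
    tau = np.inf if side["tau"] is None else float(side["tau"])
    return ATIPCSample(
        z=df["time"].to_numpy(dtype=float),
        s_applied=df["removed"].to_numpy(dtype=int),
        s_star=int(side["s_star"]),
        tau=tau,
        n=int(side["n"]),
        m=int(side["m"]),
    )
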