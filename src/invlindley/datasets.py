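"""Bundled reference datasets and their censored sub-samples.

Two classic reliability datasets ship with the package:

* ``rme_full`` — 30 times between failures of repairable mechanical
  equipment (engineering application);
* ``art_act_full`` — 40 active repair times of an airborne
  communication transceiver (physics/engineering application);

plus three adaptively Type-I progressively censored sub-samples of each
(``rme_S1..S3`` with n=30, m=15; ``art_S1..S3`` with n=40, m=20),
each defined by a removal scheme and threshold tau.  The censored
fixtures are validated against their plans on load, so the printed S*
accounting is checked every time.
"""

from __future__ import annotations

import numpy as np

from .censoring import ATIPCSample, CensoringPlan, complete_sample, from_observations

__all__ = ["load_fixture", "available_fixtures", "RME_TIMES", "ART_ACT_TIMES"]

RME_TIMES = (
    0.11, 0.30, 0.40, 0.45, 0.59, 0.63, 0.70, 0.71, 0.74, 0.77,
    0.94, 1.06, 1.17, 1.23, 1.23, 1.24, 1.43, 1.46, 1.49, 1.74,
    1.82, 1.86, 1.97, 2.23, 2.37, 2.46, 2.63, 3.46, 4.36, 4.73,
)

ART_ACT_TIMES = (
    0.50, 0.60, 0.60, 0.70, 0.70, 0.70, 0.80, 0.80, 1.00, 1.00,
    1.00, 1.00, 1.10, 1.30, 1.50, 1.50, 1.50, 1.50, 2.00, 2.00,
    2.20, 2.50, 2.70, 3.00, 3.00, 3.30, 4.00, 4.00, 4.50, 4.70,
    5.00, 5.40, 5.40, 7.00, 7.50, 8.80, 9.00, 10.2, 22.0, 24.50,
)

# (times, scheme, tau) for the censored sub-samples; n and m per dataset.
_RME_SUBSAMPLES = {
    "rme_S1": (
        (0.11, 0.30, 0.45, 0.59, 0.74, 0.77, 1.06, 1.17, 1.23, 1.46),
        (3,) * 5 + (0,) * 9,
        1.5,
    ),
    "rme_S2": (
        (0.11, 0.30, 0.40, 0.45, 0.59, 0.63, 0.71, 0.74, 0.94, 1.17, 1.49, 1.74),
        (0,) * 5 + (3,) * 5 + (0,) * 4,
        1.8,
    ),
    "rme_S3": (
        (0.11, 0.30, 0.40, 0.45, 0.59, 0.63, 0.70, 0.71, 0.74, 0.77,
         0.94, 1.06, 1.24, 1.46, 1.74, 1.86, 1.97),
        (0,) * 10 + (3,) * 4,
        2.1,
    ),
}

_ART_SUBSAMPLES = {
    "art_S1": (
        (0.50, 0.60, 0.70, 0.80, 1.00, 1.00, 1.30, 1.50, 1.50, 2.00,
         2.70, 3.00, 3.30, 4.00, 4.70),
        (5,) * 4 + (0,) * 15,
        4.8,
    ),
    "art_S2": (
        (0.50, 0.60, 0.60, 0.70, 0.70, 0.70, 0.80, 0.80, 1.00, 1.00,
         1.30, 1.50, 1.50, 2.00, 2.50, 2.70, 3.30),
        (0,) * 8 + (5,) * 4 + (0,) * 7,
        3.4,
    ),
    "art_S3": (
        (0.50, 0.60, 0.60, 0.70, 0.70, 0.70, 0.80, 0.80, 1.00, 1.00,
         1.00, 1.00, 1.10, 1.30, 1.50, 1.50, 1.50, 2.00, 2.20, 2.70,
         3.00, 3.30, 4.00, 4.50),
        (0,) * 16 + (5,) * 3,
        4.6,
    ),
}


def available_fixtures() -> list:
    return (["rme_full", "art_act_full"]
            + sorted(_RME_SUBSAMPLES) + sorted(_ART_SUBSAMPLES))


def load_fixture(name: str) -> ATIPCSample:
    """Load a bundled sample by name; censored fixtures are re-validated."""
    if name == "rme_full":
        return complete_sample(np.asarray(RME_TIMES))
    if name == "art_act_full":
        return complete_sample(np.asarray(ART_ACT_TIMES))
    if name in _RME_SUBSAMPLES:
        times, scheme, tau = _RME_SUBSAMPLES[name]
        plan = CensoringPlan(n=30, m=15, scheme=scheme[:14], tau=tau)
        return from_observations(np.asarray(times), plan)
    if name in _ART_SUBSAMPLES:
        times, scheme, tau = _ART_SUBSAMPLES[name]
        plan = CensoringPlan(n=40, m=20, scheme=scheme[:19], tau=tau)
        return from_observations(np.asarray(times), plan)
    raise KeyError(
        f"unknown fixture {name!r}; available: {', '.join(available_fixtures())}"
    )
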