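"""Small statistical utilities behind the cohort reports.

Covers the resampling-rate arithmetic (how many repeat AVS procedures per
100 remain once the decision model interprets most failed samplings), the
post-hoc two-proportion power calculation, and proportion confidence
intervals for reported fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "PowerSpec",
    "resampling_rate",
    "power_sample_size",
    "simulated_power",
    "proportion_ci",
]


@dataclass(frozen=True)
class PowerSpec:
    """Two-proportion comparison for a post-hoc power calculation."""

    p1: float  # cure rate, intervention group
    p2: float  # cure rate, reference group
    alpha: float = 0.05
    power: float = 0.80
    sidedness: str = "two_sided"

    def __post_init__(self):
        if not (0.0 < self.p2 < self.p1 < 1.0):
            raise ValueError(f"need 0 < p2 < p1 < 1, got p1={self.p1}, p2={self.p2}")
        if not (0.0 < self.alpha < 0.5):
            raise ValueError(f"alpha must be in (0, 0.5), got {self.alpha}")
        if not (0.5 < self.power < 1.0):
            raise ValueError(f"power must be in (0.5, 1), got {self.power}")
        if self.sidedness not in ("two_sided", "one_sided"):
            raise ValueError(f"sidedness must be two_sided or one_sided, got {self.sidedness!r}")


def resampling_rate(failure_rate: float, interpretable_fraction: float) -> float:
    """Repeat procedures per 100 AVS: 100 x failure x (1 - interpretable).

    ``failure_rate`` is the fraction of procedures with failed right-sided
    cannulation; ``interpretable_fraction`` the share of those the decision
    model can still call.  E.g. 30% failures of which 70% are interpretable
    leaves 9 resamplings per 100 procedures.
    """
    for name, v in (("failure_rate", failure_rate),
                    ("interpretable_fraction", interpretable_fraction)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return 100.0 * failure_rate * (1.0 - interpretable_fraction)


def _z(p: float) -> float:
    return float(stats.norm.ppf(p))


def _normal_approx_n(spec: PowerSpec) -> float:
    """Unrounded per-group n from the pooled-variance normal approximation."""
    alpha = spec.alpha / 2.0 if spec.sidedness == "two_sided" else spec.alpha
    za, zb = _z(1.0 - alpha), _z(spec.power)
    p1, p2 = spec.p1, spec.p2
    pbar = (p1 + p2) / 2.0
    num = za * math.sqrt(2.0 * pbar * (1.0 - pbar)) + zb * math.sqrt(
        p1 * (1.0 - p1) + p2 * (1.0 - p2)
    )
    return (num / (p1 - p2)) ** 2


def simulated_power(
    n: int, spec: PowerSpec, reps: int = 10_000, seed: Optional[int] = None
) -> float:
    """Monte-Carlo power of the continuity-corrected two-proportion test at n per group."""
    rng = np.random.default_rng(seed)
    alpha = spec.alpha / 2.0 if spec.sidedness == "two_sided" else spec.alpha
    zcrit = _z(1.0 - alpha)
    x1 = rng.binomial(n, spec.p1, reps)
    x2 = rng.binomial(n, spec.p2, reps)
    p1h, p2h = x1 / n, x2 / n
    pbar = (x1 + x2) / (2.0 * n)
    num = np.abs(p1h - p2h) - 1.0 / n  # Yates continuity correction, equal n
    num = np.maximum(num, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = num / np.sqrt(pbar * (1.0 - pbar) * (2.0 / n))
    zstat = np.nan_to_num(zstat, nan=0.0)
    return float((zstat > zcrit).mean())


def power_sample_size(
    spec: PowerSpec,
    method: str = "continuity_corrected",
    reps: int = 20_000,
    seed: Optional[int] = None,
    n_max: int = 10_000,
) -> int:
    """Smallest per-group n achieving the requested power.

    ``normal_approx`` is the pooled normal approximation; ``continuity_corrected``
    applies the Fleiss correction to it; ``simulation`` searches with a seeded
    Monte-Carlo of the continuity-corrected two-proportion test as the oracle.
    """
    n_raw = _normal_approx_n(spec)
    if method == "normal_approx":
        return math.ceil(n_raw)
    if method == "continuity_corrected":
        delta = abs(spec.p1 - spec.p2)
        n_cc = n_raw / 4.0 * (1.0 + math.sqrt(1.0 + 4.0 / (n_raw * delta))) ** 2
        return math.ceil(n_cc)
    if method != "simulation":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    n = max(2, math.ceil(n_raw) - 10)
    while n <= n_max:
        pw = simulated_power(n, spec, reps=reps, seed=int(rng.integers(0, 2**31 - 1)))
        if pw >= spec.power:
            return n
        n += 1
    raise RuntimeError(f"requested power not reached by n={n_max} per group")


def proportion_ci(
    successes: int,
    n: int,
    level: float = 0.95,
    method: str = "wilson",
    n_boot: int = 5_000,
    seed: Optional[int] = None,
) -> tuple[float, float]:
    """Two-sided confidence interval for a binomial proportion, clipped to [0, 1]."""
    if n < 1 or not (0 <= successes <= n):
        raise ValueError(f"invalid counts: {successes}/{n}")
    if method == "wilson":
        low, high = proportion_confint(successes, n, alpha=1.0 - level, method="wilson")
        return float(np.clip(low, 0, 1)), float(np.clip(high, 0, 1))
    if method != "bootstrap":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    draws = rng.binomial(n, successes / n, n_boot) / n
    alpha = 1.0 - level
    low, high = np.quantile(draws, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(np.clip(low, 0, 1)), float(np.clip(high, 0, 1))
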