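"""Statistical design calculator for subsample-based taxonomic profiling.

Under the *perfect-alignment model* — every sampled read maps to its true
source taxon — the number of reads from a taxon of true proportion ``q`` in
one subsample of ``m`` reads is Binomial(m, q).  The taxon is *present* in
an iteration if at least one of its reads is drawn, which happens with
probability

    pi = 1 - (1 - q)^m

Across ``i`` independent iterations the number of presences X is
Binomial(i, pi), and the taxon is *retained* by the census filter when
X > p*i (strictly more than a fraction ``p`` of the iterations).  Detection
power is therefore the exact binomial tail P(X > p*i).

The pooled abundance estimator is the mean of per-iteration sample
proportions, which for equal subsample sizes equals T/(m*i) with
T ~ Binomial(m*i, q); its mean absolute error E|T/(m*i) - q| is computed by
full pmf summation.  Monte-Carlo counterparts of both quantities are
provided for cross-checking and for the confidence-interval margin of the
implemented across-iteration interval, which has no closed form.

The strict-inequality retention boundary is shared with the census module
through :func:`retention_threshold`, so the calculator and the profiler can
never disagree on the boundary case.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DesignSpec",
    "PowerEstimate",
    "retention_threshold",
    "presence_probability",
    "detection_power",
    "estimation_error",
    "simulate_design",
    "recommend_subsample_size",
    "design_table",
]

#: Largest m*i for which the exact mean-absolute-error summation is attempted.
EXACT_MAE_LIMIT = 10_000_000

# Normal-approximation multiplier for the 95% interval used by the census.
Z_95 = 1.959963984540054


def retention_threshold(p: float, i: int) -> float:
    """Presence-count threshold: retained iff presence_count > this value.

    Snaps float dust (p*i = 40.000000000000006) back onto the integer so the
    strict inequality behaves exactly at the boundary.
    """
    threshold = p * i
    if abs(threshold - round(threshold)) < 1e-9:
        threshold = float(round(threshold))
    return threshold


@dataclass(frozen=True)
class DesignSpec:
    """One design point: true proportion q, subsample size m, iterations i,
    presence threshold p."""

    q: float
    m: int
    i: int
    p: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 <= self.q <= 1.0):
            raise ValueError(f"q must be in [0, 1], got {self.q}")
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if self.i < 1:
            raise ValueError(f"i must be >= 1, got {self.i}")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p must be in [0, 1], got {self.p}")


@dataclass(frozen=True)
class PowerEstimate:
    """Detection power and estimation error at one design point."""

    spec: DesignSpec
    presence_prob: float
    power: float
    mae: float
    method: str  # "exact" | "monte_carlo"
    reps: Optional[int] = None
    seed: Optional[int] = None
    ci_margin: Optional[float] = None  # Monte-Carlo mean of the 1.96*sd margin


def presence_probability(q: float, m: int) -> float:
    """P(taxon of proportion q appears in a subsample of m reads) = 1-(1-q)^m."""
    if not (0.0 <= q <= 1.0):
        raise ValueError(f"q must be in [0, 1], got {q}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return 1.0 - (1.0 - q) ** m


def detection_power(spec: DesignSpec) -> PowerEstimate:
    """Exact retention probability P(X > p*i), X ~ Binomial(i, pi)."""
    pi = presence_probability(spec.q, spec.m)
    power = float(stats.binom.sf(retention_threshold(spec.p, spec.i), spec.i, pi))
    mae = estimation_error(spec.q, spec.m, spec.i)
    return PowerEstimate(spec=spec, presence_prob=pi, power=power, mae=mae, method="exact")


def estimation_error(q: float, m: int, i: int) -> float:
    """Exact E|T/(m*i) - q| for T ~ Binomial(m*i, q), by full pmf summation."""
    if not (0.0 <= q <= 1.0):
        raise ValueError(f"q must be in [0, 1], got {q}")
    total = m * i
    if total > EXACT_MAE_LIMIT:
        raise ValueError(
            f"m*i = {total} exceeds the exact-summation limit "
            f"({EXACT_MAE_LIMIT}); use simulate_design for a Monte-Carlo estimate"
        )
    t = np.arange(total + 1)
    pmf = stats.binom.pmf(t, total, q)
    return float(np.sum(np.abs(t / total - q) * pmf))


def simulate_design(
    spec: DesignSpec,
    reps: int = 100_000,
    seed: int = 0,
    batch: int = 20_000,
) -> PowerEstimate:
    """Monte-Carlo power, MAE and CI margin under the perfect-alignment model.

    Each replicate draws ``i`` iteration counts ~ Binomial(m, q), applies
    the presence rule (count >= 1) and the strict retention threshold, and
    pools the proportions.  ``ci_margin`` is the Monte-Carlo mean of the
    across-iteration normal-approximation margin ``1.96 * sd`` that the
    census module attaches to its abundance estimates.
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    rng = np.random.default_rng(seed)
    threshold = retention_threshold(spec.p, spec.i)
    retained = 0
    abs_err_sum = 0.0
    margin_sum = 0.0
    done = 0
    while done < reps:
        size = min(batch, reps - done)
        counts = rng.binomial(spec.m, spec.q, size=(size, spec.i))
        presences = (counts >= 1).sum(axis=1)
        retained += int(np.count_nonzero(presences > threshold))
        fractions = counts / spec.m
        pooled = fractions.mean(axis=1)
        abs_err_sum += float(np.abs(pooled - spec.q).sum())
        if spec.i > 1:
            margin_sum += float((Z_95 * fractions.std(axis=1, ddof=1)).sum())
        done += size
    return PowerEstimate(
        spec=spec,
        presence_prob=presence_probability(spec.q, spec.m),
        power=retained / reps,
        mae=abs_err_sum / reps,
        method="monte_carlo",
        reps=reps,
        seed=seed,
        ci_margin=margin_sum / reps if spec.i > 1 else None,
    )


def recommend_subsample_size(
    q: float,
    i: int,
    p: float = 0.8,
    target_power: float = 0.99,
    max_m: int = 2**24,
) -> int:
    """Smallest m whose exact detection power reaches *target_power*.

    Found by doubling until the target is met, then bisection.  Raises if
    the target is unreachable (q = 0, or p*i >= i so retention is
    impossible, or m would exceed *max_m*).
    """
    if not (0.0 < target_power < 1.0):
        raise ValueError(f"target_power must be in (0, 1), got {target_power}")
    if q <= 0.0:
        raise ValueError("q = 0: the taxon can never be detected")

    def power_at(m: int) -> float:
        pi = presence_probability(q, m)
        return float(stats.binom.sf(retention_threshold(p, i), i, pi))

    if power_at(max_m) < target_power:
        raise ValueError(
            f"target power {target_power} unreachable with i={i}, p={p} "
            f"(even m={max_m} gives {power_at(max_m):.4f})"
        )
    hi = 1
    while power_at(hi) < target_power:
        hi *= 2
    lo = hi // 2  # power(lo) < target <= power(hi); lo=0 means hi=1 suffices
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_at(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    return hi


def design_table(
    qs: Sequence[float],
    ms: Sequence[int],
    i: int,
    p: float = 0.8,
) -> pd.DataFrame:
    """Exact power and MAE over a (q, m) grid, one row per cell."""
    if not qs or not ms:
        raise ValueError("q and m grids must be non-empty")
    rows: List[dict] = []
    for q in qs:
        for m in ms:
            est = detection_power(DesignSpec(q=q, m=m, i=i, p=p))
            rows.append(
                {
                    "q": q,
                    "m": m,
                    "i": i,
                    "p": p,
                    "presence_prob": est.presence_prob,
                    "power": est.power,
                    "mae": est.mae,
                }
            )
    return pd.DataFrame(rows)
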