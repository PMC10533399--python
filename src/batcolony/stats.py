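"""Shared resampling and exact-test primitives.

Pure-library module: the exact conditional test for two Poisson rates,
label-permutation tests, and circular-shift null generation.  These are the
inferential building blocks used by the proximity, social-modulation,
spatial-shuffle and population analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "CountPair",
    "c_test_poisson",
    "permutation_diff_test",
    "circular_shift_null",
]


@dataclass(frozen=True)
class CountPair:
    """Spike counts and exposures for two conditions.

    Attributes
    ----------
    x1, x2 : int
        Event (spike) counts in each condition.
    t1, t2 : float
        Total exposure (seconds) in each condition.
    """

    x1: int
    x2: int
    t1: float
    t2: float

    def __post_init__(self) -> None:
        if self.x1 < 0 or self.x2 < 0:
            raise ValueError("counts must be non-negative")
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError("exposures must be positive")


def c_test_poisson(pair: CountPair) -> float:
    """Exact conditional test (C-test) comparing two Poisson rates.

    Conditional on the total count k = x1 + x2, x1 is Binomial(k, t1/(t1+t2))
    under the null of equal rates (Przyborowski-Wilenski).  Two-sided p-value
    by doubling the smaller exact tail, capped at 1.

    Returns 1.0 for the degenerate k = 0 case (no information).
    """
    k = pair.x1 + pair.x2
    if k == 0:
        return 1.0
    q = pair.t1 / (pair.t1 + pair.t2)
    lower = sps.binom.cdf(pair.x1, k, q)
    upper = sps.binom.sf(pair.x1 - 1, k, q)  # P(X >= x1)
    return float(min(1.0, 2.0 * min(lower, upper)))


def permutation_diff_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = 0,
    statistic: str = "mean",
) -> float:
    """Two-sample permutation test on the difference of group means.

    p = (1 + #{|perm stat| >= |obs|}) / (n_perm + 1); the +1 correction keeps
    p strictly positive, with floor 1/(n_perm+1).
    """
    rng = np.random.default_rng(seed)
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    n_a = a.size

    obs = abs(a.mean() - b.mean())
    # vectorised permutations: argsort of uniforms gives random permutations
    u = rng.random((n_perm, pooled.size))
    order = np.argsort(u, axis=1)
    perm = pooled[order]
    stat = np.abs(perm[:, :n_a].mean(axis=1) - perm[:, n_a:].mean(axis=1))
    n_ge = int(np.sum(stat >= obs - 1e-12))
    return (1 + n_ge) / (n_perm + 1)


def circular_shift_null(
    event_times: np.ndarray,
    span: float,
    n: int = 1000,
    min_shift: float = 0.0,
    seed: int | np.random.Generator | None = 0,
) -> list[np.ndarray]:
    """Circularly shifted copies of an event-time series.

    Each surrogate adds a uniform random offset in [min_shift, span-min_shift)
    modulo ``span``, preserving the event count and all inter-event intervals
    up to the single wrap-around.
    """
    if span <= 0:
        raise ValueError("span must be positive")
    if not 0 <= min_shift < span / 2:
        raise ValueError("min_shift must lie in [0, span/2)")
    rng = np.random.default_rng(seed)
    t = np.asarray(event_times, dtype=float)
    shifts = rng.uniform(min_shift, span - min_shift, size=n)
    return [np.sort((t + s) % span) for s in shifts]
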