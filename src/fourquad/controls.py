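"""Binomial control estimators of "at least m of T agreements".

Both controls extend the conventional concordance rate to repeated
measurements by treating each time point's trend agreement as a Bernoulli
event:

* control1 pools the agreement counts into a single success probability
  p = (sum k_t) / (sum n_t-dagger) and returns the binomial upper tail
  P(#successes >= m) with T trials.
* control2 keeps a per-time probability p_t = k_t / n_t-dagger and returns
  the tail of the sum of independent, non-identical Bernoulli indicators
  (a Poisson-binomial tail; for T = 2, m = 2 this is p1*p2, and for m = 1
  it is p1*p2 + p1*(1-p2) + (1-p1)*p2).

Subjects whose difference pair falls inside the exclusion zone at ANY time
point are excluded from both controls, mirroring the conditioning event of
the model-based rate.  A per-time eligibility variant (subject counted at
time t whenever its time-t point is outside the zone) is available through
``per_time=True`` for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import DifferencePairs
from .errors import UndefinedRateError

__all__ = [
    "ControlInputs",
    "count_control_inputs",
    "control1_rate",
    "control2_rate",
]


@dataclass(frozen=True)
class ControlInputs:
    """Per-time agreement counts k_t and eligible-subject counts n_t-dagger."""

    k: np.ndarray
    n_dagger: np.ndarray

    def __post_init__(self):
        k = np.asarray(self.k, dtype=int)
        nd = np.asarray(self.n_dagger, dtype=int)
        object.__setattr__(self, "k", k)
        object.__setattr__(self, "n_dagger", nd)
        if k.shape != nd.shape or k.ndim != 1:
            raise ValueError("k and n_dagger must be 1-d arrays of equal length")
        if np.any(k < 0) or np.any(k > nd):
            raise ValueError("counts must satisfy 0 <= k_t <= n_t_dagger")

    @property
    def T(self) -> int:
        return self.k.size


def count_control_inputs(
    diffs: DifferencePairs, a: float, *, per_time: bool = False
) -> ControlInputs:
    """Count agreements and eligible subjects per time point.

    With the default any-time rule, a subject is eligible only if none of its
    T points falls in the closed exclusion square, so n_t-dagger is constant
    in t.  With ``per_time=True``, eligibility is assessed time by time.
    """
    in_ez = (np.abs(diffs.x) <= a) & (np.abs(diffs.y) <= a)  # (n, T)
    agree = ((diffs.x >= 0) & (diffs.y >= 0)) | ((diffs.x < 0) & (diffs.y < 0))
    if per_time:
        eligible = ~in_ez
    else:
        eligible = np.repeat(
            ~in_ez.any(axis=1, keepdims=True), diffs.n_times, axis=1
        )
    n_dagger = eligible.sum(axis=0)
    k = (agree & eligible).sum(axis=0)
    if not np.any(n_dagger > 0):
        raise UndefinedRateError(
            "no subject remains outside the exclusion zone",
            n_subjects=diffs.n_subjects,
        )
    return ControlInputs(k=k, n_dagger=n_dagger)


def control1_rate(inputs: ControlInputs, m: int) -> float:
    """Binomial tail with pooled success probability p = sum(k)/sum(n_dagger)."""
    total = int(inputs.n_dagger.sum())
    if total == 0:
        raise UndefinedRateError("all eligible-subject counts are zero")
    T = inputs.T
    if not 1 <= m <= T:
        raise ValueError("m must satisfy 1 <= m <= T")
    p = inputs.k.sum() / total
    # P(X >= m) for X ~ Binomial(T, p)
    return float(stats.binom.sf(m - 1, T, p))


def control2_rate(inputs: ControlInputs, m: int) -> float:
    """Poisson-binomial tail with per-time probabilities p_t = k_t/n_t-dagger."""
    if np.any(inputs.n_dagger == 0):
        raise UndefinedRateError("an eligible-subject count n_t_dagger is zero")
    T = inputs.T
    if not 1 <= m <= T:
        raise ValueError("m must satisfy 1 <= m <= T")
    p = inputs.k / inputs.n_dagger
    # Exact distribution of the number of successes by polynomial convolution.
    pmf = np.array([1.0])
    for pt in p:
        pmf = np.convolve(pmf, [1.0 - pt, pt])
    # convolution round-off can leave the tail an ulp outside [0, 1]
    return float(np.clip(pmf[m:].sum(), 0.0, 1.0))
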