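"""Model-based concordance rate under a multivariate normal model.

The 2T difference variables Z = (X_1..X_T, Y_1..Y_T) of a subject are
modelled jointly as N(mean, covariance).  The concordance rate is the
conditional probability that at least m of the T time points show trend
agreement, given that no time point's pair falls in the exclusion zone:

    P[ union_{t=m..T} H_t | NEz(a) ]
        = sum_{t=m..T} P[H_t ∩ NEz(a)] / (1 - P[ union_s Ez_s(a) ])

where H_t is the event of exactly t agreeing time points and Ez_s(a) the
event that the time-s pair lies in the closed square [-a, a]^2.

Every term reduces to signed axis-aligned rectangle probabilities.  Per time
point the indicator of "in an agreement (resp. disagreement) quadrant and
outside the exclusion zone" is a sum of two quadrant rectangles minus the
two exclusion-zone cells they contain; the product over the T time points
expands into at most 4^T signed 2T-dimensional rectangles.  The denominator
uses inclusion-exclusion over subsets of time points.  All rectangle
probabilities are evaluated with the quasi-Monte-Carlo integrator in
:mod:`fourquad.integrate`.

Parameters are estimated from the data by the sample mean and the unbiased
sample covariance of the stacked difference vectors — including points
inside the exclusion zone, since the conditioning handles the zone at the
probability level rather than by discarding data.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import AnalysisConfig, DifferencePairs
from .errors import EstimationError, NumericalError, UndefinedRateError
from .integrate import mvn_rectangle_probabilities

__all__ = [
    "MVNParams",
    "SignedRectangle",
    "AgreementPattern",
    "ProposedRateResult",
    "estimate_mvn_params",
    "rectangle_probability",
    "enumerate_numerator_rectangles",
    "proposed_rate",
    "proposed_rate_from_data",
    "MAX_T",
]

#: Largest supported number of differences for the exact signed-rectangle
#: expansion; the rectangle count grows as ~2^T * 4^T.
MAX_T = 6

#: Relative ridge threshold: if the smallest eigenvalue of the sample
#: covariance falls below this times the mean diagonal, a ridge of that
#: magnitude is added.
_RIDGE_REL = 1e-8


@dataclass(frozen=True)
class MVNParams:
    """Mean vector and covariance of Z = (X_1..X_T, Y_1..Y_T)."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=float).ravel()
        cov = np.asarray(self.covariance, dtype=float)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)
        d = mean.size
        if d % 2 != 0 or d == 0:
            raise ValueError("mean must have even length 2T")
        if cov.shape != (d, d):
            raise ValueError("covariance must be (2T, 2T)")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(cov).min() < -1e-10:
            raise ValueError("covariance must be positive semi-definite")

    @property
    def T(self) -> int:
        return self.mean.size // 2

    def swap_methods(self) -> "MVNParams":
        """Exchange the X-block and Y-block (swap the two methods)."""
        T = self.T
        perm = np.r_[np.arange(T, 2 * T), np.arange(T)]
        return MVNParams(self.mean[perm], self.covariance[np.ix_(perm, perm)])


@dataclass(frozen=True)
class SignedRectangle:
    """An axis-aligned box in 2T dimensions with a +1/-1 weight."""

    lower: np.ndarray
    upper: np.ndarray
    weight: int

    def __post_init__(self):
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if np.any(lower > upper):
            raise ValueError("empty rectangle: lower > upper")
        if self.weight not in (-1, 1):
            raise ValueError("weight must be +1 or -1")


@dataclass(frozen=True)
class AgreementPattern:
    """Which of the T time points are in trend agreement."""

    agrees: tuple

    @property
    def n_agree(self) -> int:
        return sum(self.agrees)


@dataclass(frozen=True)
class ProposedRateResult:
    """Model-based concordance rate with its numerator decomposition."""

    rate: float
    numerator: float
    denominator: float
    per_t_numerators: np.ndarray
    integration_error: float

    def to_dict(self) -> dict:
        return {
            "rate": self.rate,
            "numerator": self.numerator,
            "denominator": self.denominator,
            "per_t_numerators": list(np.asarray(self.per_t_numerators)),
            "integration_error": self.integration_error,
        }


def estimate_mvn_params(diffs: DifferencePairs) -> MVNParams:
    """Sample mean and unbiased covariance of the stacked difference vectors.

    All subjects contribute, including those with points inside the
    exclusion zone.
    """
    n = diffs.n_subjects
    if n < 2:
        raise EstimationError("at least two subjects are needed to estimate a covariance")
    z = np.hstack([diffs.x, diffs.y])  # (n, 2T)
    mean = z.mean(axis=0)
    cov = np.cov(z, rowvar=False, ddof=1)
    return MVNParams(mean=mean, covariance=np.atleast_2d(cov))


def _regularized_cov(cov: np.ndarray) -> np.ndarray:
    """Add a small ridge when the covariance is (near-)singular."""
    scale = float(np.mean(np.diag(cov)))
    floor = _RIDGE_REL * scale if scale > 0 else 1e-12
    min_eig = np.linalg.eigvalsh(cov).min()
    if min_eig < floor:
        ridge = max(floor, -min_eig + floor, 1e-12)
        warnings.warn(
            f"near-singular covariance (min eigenvalue {min_eig:.3g}); "
            f"adding ridge {ridge:.3g}",
            RuntimeWarning,
            stacklevel=3,
        )
        cov = cov + ridge * np.eye(cov.shape[0])
    return cov


def rectangle_probability(
    params: MVNParams,
    lower: Sequence[float],
    upper: Sequence[float],
    *,
    tol: float = 1e-6,
) -> tuple[float, float]:
    """P(lower < Z < upper) under the fitted normal, with an error estimate."""
    cov = _regularized_cov(params.covariance)
    probs, errs = mvn_rectangle_probabilities(
        params.mean, cov, np.atleast_2d(lower), np.atleast_2d(upper), tol=tol
    )
    return float(probs[0]), float(errs[0])


# Per-time 2-d boxes, as ((x_lo, x_hi), (y_lo, y_hi), weight).
def _time_boxes(agree: bool, a: float):
    inf = np.inf
    if agree:
        return (
            ((0.0, inf), (0.0, inf), +1),    # quadrant A
            ((-inf, 0.0), (-inf, 0.0), +1),  # quadrant B
            ((0.0, a), (0.0, a), -1),        # EzA
            ((-a, 0.0), (-a, 0.0), -1),      # EzB
        )
    return (
        ((-inf, 0.0), (0.0, inf), +1),   # quadrant C
        ((0.0, inf), (-inf, 0.0), +1),   # quadrant D
        ((-a, 0.0), (0.0, a), -1),       # EzC
        ((0.0, a), (-a, 0.0), -1),       # EzD
    )


def enumerate_numerator_rectangles(
    pattern: AgreementPattern, a: float, T: int
) -> list[SignedRectangle]:
    """Signed rectangles whose weighted probabilities sum to
    P[agreement exactly per ``pattern`` and all time points outside Ez(a)].

    Coordinates are ordered (X_1..X_T, Y_1..Y_T): time t occupies dimensions
    t and T + t.  The expansion is the product over time points of
    (quadrant1 + quadrant2 - excluded-cell1 - excluded-cell2), i.e. at most
    4^T rectangles.
    """
    if len(pattern.agrees) != T:
        raise ValueError("pattern length must equal T")
    if a < 0:
        raise ValueError("a must be >= 0")
    per_time = [_time_boxes(bool(g), a) for g in pattern.agrees]
    rects = []
    for combo in itertools.product(*per_time):
        lower = np.empty(2 * T)
        upper = np.empty(2 * T)
        weight = 1
        for t, (xb, yb, w) in enumerate(combo):
            lower[t], upper[t] = xb
            lower[T + t], upper[T + t] = yb
            weight *= w
        rects.append(SignedRectangle(lower=lower, upper=upper, weight=weight))
    return rects


def _denominator_rectangles(a: float, T: int) -> list[SignedRectangle]:
    """Inclusion-exclusion rectangles for P[union_s Ez_s(a)].

    Each nonempty subset S of time points contributes the rectangle
    with [-a, a] bounds on (X_s, Y_s) for s in S and infinite bounds
    elsewhere, with weight (-1)^(|S|+1).
    """
    rects = []
    for r in range(1, T + 1):
        for subset in itertools.combinations(range(T), r):
            lower = np.full(2 * T, -np.inf)
            upper = np.full(2 * T, np.inf)
            for s in subset:
                lower[s], upper[s] = -a, a
                lower[T + s], upper[T + s] = -a, a
            rects.append(
                SignedRectangle(lower=lower, upper=upper, weight=1 if r % 2 else -1)
            )
    return rects


def proposed_rate(
    params: MVNParams,
    config: AnalysisConfig,
    *,
    denom_floor: float = 1e-10,
    tol: float = 1e-6,
    qmc_options: dict | None = None,
) -> ProposedRateResult:
    """Model-based concordance rate P[>= m of T agreements | NEz(a)].

    Parameters
    ----------
    params : fitted (or assumed) normal model of the 2T difference vector.
    config : exclusion-zone half-width ``a``, number of differences ``T``
        and minimum agreement count ``m``.
    denom_floor : smallest admissible denominator; below it the model mass
        is essentially confined to the exclusion zone and the conditional
        probability is undefined.
    tol : absolute integration accuracy target per rectangle.
    qmc_options : extra keyword arguments for the rectangle integrator
        (``n_base``, ``n_shifts``, ``max_base``, ``seed``) to trade accuracy
        for speed in large simulation sweeps.
    """
    T = config.T
    if params.T != T:
        raise ValueError(f"params describe T={params.T} but config has T={config.T}")
    if T > MAX_T:
        raise NumericalError(
            f"T={T} exceeds the exact-expansion cap MAX_T={MAX_T}; "
            "the rectangle count ~2^T*4^T is impractical beyond it"
        )
    cov = _regularized_cov(params.covariance)
    opts = qmc_options or {}

    # Collect every rectangle (numerator patterns + denominator) for one
    # batched integrator call.
    patterns = [
        AgreementPattern(agrees=combo)
        for combo in itertools.product((False, True), repeat=T)
        if sum(combo) >= config.m
    ]
    pattern_rects = [
        enumerate_numerator_rectangles(p, config.a, T) for p in patterns
    ]
    denom_rects = _denominator_rectangles(config.a, T)
    all_rects = [r for group in pattern_rects for r in group] + denom_rects
    lower = np.array([r.lower for r in all_rects])
    upper = np.array([r.upper for r in all_rects])
    weights = np.array([r.weight for r in all_rects], dtype=float)
    probs, errs = mvn_rectangle_probabilities(
        params.mean, cov, lower, upper, tol=tol, **opts
    )

    signed = weights * probs
    # Per-pattern sums, aggregated by number of agreements t = m..T.
    per_t = np.zeros(T - config.m + 1)
    pos = 0
    for p, group in zip(patterns, pattern_rects):
        s = float(signed[pos : pos + len(group)].sum())
        per_t[p.n_agree - config.m] += s
        pos += len(group)
    # Cancellation in the signed sums can leave tiny negatives.
    clip_tol = 10 * tol
    if np.any(per_t < -clip_tol):
        warnings.warn(
            f"numerator clipping beyond integration tolerance "
            f"(min {per_t.min():.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    per_t = np.clip(per_t, 0.0, 1.0)
    numerator = float(per_t.sum())

    p_union_ez = float(signed[pos:].sum())
    denominator = 1.0 - p_union_ez
    integration_error = float(np.abs(errs).sum())
    if denominator < denom_floor:
        raise UndefinedRateError(
            "the fitted distribution is concentrated in the exclusion zone; "
            "the conditional concordance rate is undefined",
            denominator=denominator,
        )
    rate = numerator / denominator
    if rate > 1.0 + clip_tol / denominator:
        warnings.warn(
            f"rate clipped from {rate:.6g} to 1; exceeds integration tolerance",
            RuntimeWarning,
            stacklevel=2,
        )
    rate = float(np.clip(rate, 0.0, 1.0))
    return ProposedRateResult(
        rate=rate,
        numerator=numerator,
        denominator=denominator,
        per_t_numerators=per_t,
        integration_error=integration_error,
    )


def proposed_rate_from_data(
    diffs: DifferencePairs,
    config: AnalysisConfig,
    **kwargs,
) -> ProposedRateResult:
    """Convenience: fit the normal model to ``diffs`` and evaluate the rate."""
    return proposed_rate(estimate_mvn_params(diffs), config, **kwargs)
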