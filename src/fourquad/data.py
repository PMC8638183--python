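"""Core data model for repeated paired measurements.

Two methods — a gold standard and an experimental technique — measure the
same n subjects at T+1 ordered time points.  The four-quadrant plot is built
from the consecutive-time differences: for subject i and time index t,

    x_it = reference[i, t+1] - reference[i, t]
    y_it = test[i, t+1]      - test[i, t]

Each (x_it, y_it) pair is a point on the plot.  Points in the upper-right
(both differences nonnegative) or lower-left (both negative) quadrants mean
the two methods changed in the same direction — "agreement".  A central
square of half-width ``a`` (the exclusion zone) marks changes too small to
trust.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "MeasurementSeries",
    "DifferencePairs",
    "AnalysisConfig",
    "QuadrantLabel",
    "compute_differences",
    "classify_point",
]


@dataclass(frozen=True)
class MeasurementSeries:
    """Raw repeated measurements of two methods on the same subjects.

    Parameters
    ----------
    subject_ids : sequence
        One identifier per subject (length n).
    times : sequence
        Ordered labels of the T+1 measurement occasions.  Differences are
        always taken in this stored order; no re-sorting is performed.
    reference_values : (n, T+1) array
        Values of the gold-standard method.
    test_values : (n, T+1) array
        Values of the experimental method.
    """

    subject_ids: Sequence
    times: Sequence
    reference_values: np.ndarray
    test_values: np.ndarray

    def __post_init__(self):
        ref = np.asarray(self.reference_values, dtype=float)
        tst = np.asarray(self.test_values, dtype=float)
        object.__setattr__(self, "reference_values", ref)
        object.__setattr__(self, "test_values", tst)
        if ref.ndim != 2 or tst.ndim != 2 or ref.shape != tst.shape:
            raise ConfigurationError(
                "reference and test value matrices must share an (n, T+1) shape"
            )
        n, k = ref.shape
        if n < 1:
            raise ConfigurationError("at least one subject is required")
        if k < 2:
            raise ConfigurationError("at least two time points are required")
        if len(self.subject_ids) != n:
            raise ConfigurationError("subject_ids length must match the row count")
        if len(self.times) != k:
            raise ConfigurationError("times length must match the column count")
        if not (np.isfinite(ref).all() and np.isfinite(tst).all()):
            raise ConfigurationError(
                "missing or non-finite values are not supported; "
                "remove incomplete subjects before analysis"
            )

    @property
    def n_subjects(self) -> int:
        return self.reference_values.shape[0]

    @property
    def n_times(self) -> int:
        return self.reference_values.shape[1]


@dataclass(frozen=True)
class DifferencePairs:
    """Consecutive-time differences (x_it, y_it): the four-quadrant points.

    ``x`` holds the gold-standard differences and ``y`` the experimental
    ones, both with shape (n, T).
    """

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        x = np.atleast_2d(np.asarray(self.x, dtype=float))
        y = np.atleast_2d(np.asarray(self.y, dtype=float))
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.shape != y.shape or x.ndim != 2:
            raise ConfigurationError("x and y must share an (n, T) shape")
        if x.shape[1] < 1:
            raise ConfigurationError("at least one difference (T >= 1) is required")

    @property
    def n_subjects(self) -> int:
        return self.x.shape[0]

    @property
    def n_times(self) -> int:
        """Number of differences T."""
        return self.x.shape[1]


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis hyper-parameters.

    a : half-width of the square exclusion zone (>= 0).
    T : number of consecutive-time differences.
    m : minimum number of per-subject trend agreements (1 <= m <= T)
        regarded as overall agreement.
    """

    a: float
    T: int
    m: int

    def __post_init__(self):
        if self.a < 0:
            raise ConfigurationError("exclusion-zone half-width a must be >= 0")
        if self.T < 1:
            raise ConfigurationError("T must be a positive integer")
        if not 1 <= self.m <= self.T:
            raise ConfigurationError("m must satisfy 1 <= m <= T")


@dataclass(frozen=True)
class QuadrantLabel:
    """Quadrant membership of a single four-quadrant point.

    Quadrants follow the closed/open convention of the region definitions:
    boundaries (x == 0 or y == 0) belong to the ">= 0" side.

    quadrant : 'A' (x>=0, y>=0), 'B' (x<0, y<0), 'C' (x<0, y>=0),
               'D' (x>=0, y<0).
    excluded : True iff -a <= x <= a and -a <= y <= a (closed square).
    """

    quadrant: str
    excluded: bool

    @property
    def agreement(self) -> bool:
        return self.quadrant in ("A", "B")


def compute_differences(series: MeasurementSeries) -> DifferencePairs:
    """Consecutive-time differences of both methods, columnwise in stored order."""
    if series.n_times < 2:
        raise ConfigurationError("need at least two time points to difference")
    return DifferencePairs(
        x=np.diff(series.reference_values, axis=1),
        y=np.diff(series.test_values, axis=1),
    )


def classify_point(x: float, y: float, a: float) -> QuadrantLabel:
    """Classify one (x, y) difference pair into a quadrant and exclusion flag."""
    if x >= 0:
        quadrant = "A" if y >= 0 else "D"
    else:
        quadrant = "C" if y >= 0 else "B"
    excluded = bool(-a <= x <= a and -a <= y <= a)
    return QuadrantLabel(quadrant=quadrant, excluded=excluded)
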