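"""Conventional concordance rate (CCR) with an exclusion zone.

The CCR pools all n*T four-quadrant points, ignoring which subject produced
them, and reports

    CCR(a) = (#SA - #AEz(a)) / (nT - #Ez(a))

where SA are points in the agreement quadrants ((x>=0, y>=0) or
(x<0, y<0)), Ez(a) the points in the closed central square [-a, a]^2, and
AEz(a) the agreement points inside the exclusion zone.  AEz uses the printed
sub-square definitions verbatim: the positive cell is closed ([0,a] x [0,a])
while the negative cell is open ((-a,0) x (-a,0)); for continuous data the
distinction is measure-zero.

Pooling across subjects is exactly what makes the CCR blind to within-subject
covariance — the limitation the model-based rate addresses — so it is
reproduced here without modification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DifferencePairs
from .errors import UndefinedRateError

__all__ = ["CCRResult", "conventional_concordance"]


@dataclass(frozen=True)
class CCRResult:
    """Conventional concordance rate and its constituent counts."""

    rate: float
    n_agreement_outside: int
    n_total_outside: int
    n_excluded: int

    def to_dict(self) -> dict:
        return {
            "rate": self.rate,
            "n_agreement_outside": self.n_agreement_outside,
            "n_total_outside": self.n_total_outside,
            "n_excluded": self.n_excluded,
        }


def conventional_concordance(diffs: DifferencePairs, a: float) -> CCRResult:
    """Compute CCR(a) over the pooled n*T difference pairs.

    Raises
    ------
    UndefinedRateError
        If every point lies in the exclusion zone (denominator zero).
    """
    x = diffs.x.ravel()
    y = diffs.y.ravel()
    n_total = x.size

    sa = ((x >= 0) & (y >= 0)) | ((x < 0) & (y < 0))
    ez = (np.abs(x) <= a) & (np.abs(y) <= a)
    aez = ((x >= 0) & (x <= a) & (y >= 0) & (y <= a)) | (
        (x > -a) & (x < 0) & (y > -a) & (y < 0)
    )

    n_sa = int(sa.sum())
    n_ez = int(ez.sum())
    n_aez = int(aez.sum())
    denom = n_total - n_ez
    if denom == 0:
        raise UndefinedRateError(
            "all points fall inside the exclusion zone; CCR is undefined",
            n_sa=n_sa,
            n_ez=n_ez,
            n_aez=n_aez,
            n_total=n_total,
        )
    return CCRResult(
        rate=(n_sa - n_aez) / denom,
        n_agreement_outside=n_sa - n_aez,
        n_total_outside=denom,
        n_excluded=n_ez,
    )
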