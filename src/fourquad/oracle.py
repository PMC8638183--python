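"""Monte Carlo oracle for the model-based concordance rate.

Estimates the same conditional probability as :func:`fourquad.mvn.proposed_rate`
by brute force: draw difference vectors from the fitted normal, classify
each draw's T pairs, and take the ratio of "at least m agreements with all
pairs outside the exclusion zone" to "all pairs outside the exclusion zone".
It shares no code with the signed-rectangle path, which makes it a genuinely
independent check; it is exposed in the API but intended for validation and
diagnostics rather than routine use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import AnalysisConfig
from .errors import UndefinedRateError
from .mvn import MVNParams

__all__ = ["MCEstimate", "mc_proposed_rate"]


@dataclass(frozen=True)
class MCEstimate:
    """Conditional Monte Carlo estimate with its binomial standard error."""

    estimate: float
    std_error: float
    n_draws: int
    n_conditional: int
    seed: int


def mc_proposed_rate(
    params: MVNParams,
    config: AnalysisConfig,
    n_draws: int = 1_000_000,
    seed: int = 0,
    *,
    chunk: int = 500_000,
) -> MCEstimate:
    """Monte Carlo estimate of P[>= m of T agreements | NEz(a)].

    The standard error uses the conditional sample size (draws surviving
    the outside-the-exclusion-zone condition).
    """
    if n_draws < 10_000:
        raise ValueError("use at least 10^4 draws for a meaningful oracle")
    T = config.T
    if params.T != T:
        raise ValueError("params and config disagree on T")
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(
        params.covariance + 1e-12 * np.eye(2 * T)
    )
    kept = 0
    hits = 0
    remaining = n_draws
    while remaining > 0:
        size = min(chunk, remaining)
        remaining -= size
        z = rng.standard_normal((size, 2 * T)) @ chol.T + params.mean
        x, y = z[:, :T], z[:, T:]
        in_ez = (np.abs(x) <= config.a) & (np.abs(y) <= config.a)
        outside = ~in_ez.any(axis=1)
        agree = ((x >= 0) & (y >= 0)) | ((x < 0) & (y < 0))
        n_agree = agree.sum(axis=1)
        kept += int(outside.sum())
        hits += int((outside & (n_agree >= config.m)).sum())
    if kept == 0:
        raise UndefinedRateError(
            "no draw survived the exclusion-zone condition", n_draws=n_draws
        )
    est = hits / kept
    se = float(np.sqrt(est * (1.0 - est) / kept))
    return MCEstimate(
        estimate=est, std_error=se, n_draws=n_draws, n_conditional=kept, seed=seed
    )
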