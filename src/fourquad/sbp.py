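"""Synthetic stand-in for a three-observer blood-pressure dataset.

Emulates the structure of the classic systolic-blood-pressure
method-comparison data: n subjects measured at three occasions by two human
observers (J, R) reading the same gold-standard instrument and by an
automatic machine (S).  The generator is Gaussian latent-plus-noise:

    L_it = subject level b_i + per-time shift s_it        (latent pressure)
    J_it = L_it + observer noise
    R_it = L_it + observer noise                          (independent of J's)
    S_it = bias + b_i + attenuation * (L_it - b_i) + machine noise

J and R share the latent trajectory, so their consecutive-time differences
track each other closely (points near the 45-degree line of the
four-quadrant plot: a concordant pair).  S couples to the latent trend only
through the attenuation factor and carries larger noise, producing the
discordant contrast.  The generator targets this qualitative structure, not
the numeric values of any real dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import MeasurementSeries

__all__ = ["SbpSimSpec", "generate_sbp_like", "pair_series"]


@dataclass(frozen=True)
class SbpSimSpec:
    """Parameters of the synthetic three-observer generator.

    Units are mmHg-like: subject levels around 120 with sd
    ``subject_level_sd``, per-time latent shifts with sd ``trend_sd``.
    """

    n_subjects: int = 85
    n_times: int = 3
    observer_noise_sd: float = 3.0
    machine_bias: float = 8.0
    machine_noise_sd: float = 12.0
    subject_level_sd: float = 15.0
    trend_sd: float = 8.0
    attenuation: float = 0.4
    base_level: float = 120.0
    seed: int = 0

    def __post_init__(self):
        for name in ("machine_noise_sd", "subject_level_sd", "trend_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.observer_noise_sd < 0:
            raise ValueError("observer_noise_sd must be nonnegative")


def generate_sbp_like(
    spec: SbpSimSpec = SbpSimSpec(),
) -> dict[str, MeasurementSeries]:
    """Generate the (J, R, S) triple; deterministic under ``spec.seed``.

    Each observer is returned as a MeasurementSeries whose reference and
    test matrices both hold that observer's values; pair two observers for
    analysis with :func:`pair_series`.
    """
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_subjects, spec.n_times
    levels = spec.base_level + spec.subject_level_sd * rng.standard_normal((n, 1))
    shifts = spec.trend_sd * rng.standard_normal((n, k))
    latent = levels + shifts

    j = latent + spec.observer_noise_sd * rng.standard_normal((n, k))
    r = latent + spec.observer_noise_sd * rng.standard_normal((n, k))
    s = (
        spec.machine_bias
        + levels
        + spec.attenuation * shifts
        + spec.machine_noise_sd * rng.standard_normal((n, k))
    )

    subject_ids = [f"subj{i + 1:03d}" for i in range(n)]
    times = list(range(1, k + 1))

    def wrap(values: np.ndarray) -> MeasurementSeries:
        return MeasurementSeries(
            subject_ids=subject_ids,
            times=times,
            reference_values=values,
            test_values=values,
        )

    return {"J": wrap(j), "R": wrap(r), "S": wrap(s)}


def pair_series(reference: MeasurementSeries, test: MeasurementSeries) -> MeasurementSeries:
    """Combine two single-observer series into a reference/test pair."""
    return MeasurementSeries(
        subject_ids=reference.subject_ids,
        times=reference.times,
        reference_values=reference.reference_values,
        test_values=test.reference_values,
    )
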