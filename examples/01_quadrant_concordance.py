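"""Conventional concordance rate and binomial controls on a tiny dataset.

Builds ten subjects measured three times by two methods, forms the
consecutive-time differences, and prints the pooled conventional
concordance rate CCR(a) together with the two subject-level binomial
controls for "at least m of 2 agreements".
"""

import numpy as np

from fourquad import (
    AnalysisConfig,
    MeasurementSeries,
    compute_differences,
    conventional_concordance,
    control1_rate,
    control2_rate,
    count_control_inputs,
)

rng = np.random.default_rng(7)
n = 10
latent = 100 + 10 * rng.standard_normal((n, 1)) + 4 * rng.standard_normal((n, 3))
series = MeasurementSeries(
    subject_ids=[f"s{i}" for i in range(n)],
    times=[1, 2, 3],
    reference_values=latent + 1.0 * rng.standard_normal((n, 3)),
    test_values=latent + 2.5 * rng.standard_normal((n, 3)),
)

diffs = compute_differences(series)
a = 1.0

ccr = conventional_concordance(diffs, a)
print(f"CCR({a}) = {ccr.rate:.3f}  "
      f"({ccr.n_agreement_outside}/{ccr.n_total_outside} agreeing points "
      f"outside the zone; {ccr.n_excluded} excluded)")

inputs = count_control_inputs(diffs, a)
for m in (1, 2):
    c1 = control1_rate(inputs, m)
    c2 = control2_rate(inputs, m)
    print(f"m={m}: control1 (pooled binomial) = {c1:.3f}, "
          f"control2 (per-time product)   = {c2:.3f}")

# CCR pools the 2n points and ignores subjects; the controls condition on
# subjects never entering the exclusion zone and model per-subject counts.
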