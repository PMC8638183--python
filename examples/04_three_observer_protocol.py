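"""Subject-resampling evaluation on synthetic three-observer data.

Generates a blood-pressure-like dataset (observers J and R reading the same
gold-standard instrument, machine S with bias, attenuated trend coupling
and larger noise), then repeatedly draws 10 subjects with replacement,
computes all four concordance estimators on the pairs (J,R), (R,S), (J,S)
with the exclusion zone set to the 10% quantile of the pooled absolute
differences, and reports how well each estimator separates the concordant
(J,R) pair from the two machine pairs.
"""

from fourquad import SbpSimSpec, bootstrap_real_protocol, generate_sbp_like

methods = generate_sbp_like(SbpSimSpec(seed=0))
table, rocs, undefined = bootstrap_real_protocol(
    methods["J"], methods["R"], methods["S"],
    n_iterations=200, subjects_per_draw=10, seed=0, m=2,
)

print("AUC of each estimator (concordant pair vs machine pairs):")
for name, roc in rocs.items():
    print(f"  {name:9s} AUC = {roc.auc:.3f}   Youden cutoff = {roc.cutoff:.3f}")
if len(undefined):
    print("\nundefined rates excluded from the ROC:")
    print(undefined.to_string(index=False))

# The model-based rate typically reaches a higher AUC than the pooled
# conventional rate: it uses the within-subject covariance the CCR ignores.
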