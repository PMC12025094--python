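"""Bland-Altman agreement between clinician scores and model predictions.

One point per subject: the difference (predicted - actual) is plotted
against the pair average, with limits of agreement at the mean difference
+/- 1.96 SD. Here predictions are simulated around the true scores to show
the computation; in a real run they come from per-subject aggregation of
window predictions (see `aggregate_subject_scores`).
"""

import numpy as np

from gaitbbs import aggregate_subject_scores, bland_altman, stratified_metrics

rng = np.random.default_rng(0)
groups = np.array(["young_hc"] * 12 + ["elderly_hc"] * 8 + ["pd"] * 8
                  + ["stroke"] * 12)
actual = np.concatenate([rng.normal(m, s, n).round() for (m, s, n) in
                         [(55.7, 0.75, 12), (50.6, 3.7, 8),
                          (47.6, 3.0, 8), (44.5, 2.5, 12)]]).clip(0, 56)

# emulate per-subject aggregation of 10 noisy window predictions each
predicted = np.array([
    aggregate_subject_scores(a + rng.normal(0, 1.5, size=10))
    for a in actual
])

ba = bland_altman(actual, predicted)
print(f"mean difference   {ba.mean_diff:+.3f} BBS points")
print(f"limits of agreement  [{ba.loa_low:+.3f}, {ba.loa_high:+.3f}]")
print(f"within limits     {ba.within_fraction:.1%} of {len(actual)} subjects")

print("\nper-group accuracy:")
for group, m in stratified_metrics(actual, predicted, groups).items():
    print(f"  {group:10s} MAE {m['mae']:5.2f}  RMSE {m['rmse']:5.2f}  (n={m['n']})")
# Export ba.averages / ba.differences to CSV for plotting the classic
# agreement figure; `gaitbbs evaluate` does exactly that.
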