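"""Rebalance an imbalanced cohort with SMOTE.

A 506/46 control/case cohort has an 8.3% case prior; classifiers trained
on it default to the majority class. SMOTE grows the minority to 300 by
interpolating between nearest minority neighbours while the majority is
undersampled to 300.
"""

import numpy as np

from ctglearn import LabelledDataset, SmoteConfig, smote_resample

rng = np.random.default_rng(0)
labels = np.concatenate([np.zeros(506, int), np.ones(46, int)])
features = rng.normal(0, 1, (552, 13))
features[labels == 1, :3] += 1.5  # weakly informative shift
data = LabelledDataset(features, labels)

print(f"before: {data.n_cases} cases / {data.n_controls} controls "
      f"(case prior {100 * data.n_cases / 552:.1f}%)")
balanced = smote_resample(data, SmoteConfig(k_neighbours=5, seed=1))
print(f"after:  {balanced.n_cases} cases / {balanced.n_controls} controls "
      f"(base rate {100 * balanced.n_cases / 600:.0f}%)")

synth = balanced.features[balanced.labels == 1][46:]
minority = data.features[labels == 1]
print(f"synthetic points: {len(synth)}; per-feature bounds respected: "
      f"{bool(np.all(synth.min(0) >= minority.min(0) - 1e-12) and np.all(synth.max(0) <= minority.max(0) + 1e-12))}")
# Every synthetic point lies on a segment between two original minority
# points, so the minority region grows without leaving its convex hull.
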