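"""Rebalance an imbalanced training matrix two ways.

Starts from a 200-positive / 1500-negative feature matrix (the shape a
curated antioxidant training set has), then shows SMOTE oversampling to
1500/1500 and random undersampling to 200/200.
"""

import numpy as np

from antioxseq import FeatureMatrix, ResampleConfig, random_undersample, smote_oversample

rng = np.random.default_rng(0)
n_pos, n_neg = 200, 1500
fm = FeatureMatrix(
    [f"s{i}" for i in range(n_pos + n_neg)],
    [f"f{j}" for j in range(8)],
    rng.random((n_pos + n_neg, 8)),
    np.array([1] * n_pos + [0] * n_neg),
)
print(f"before: {n_pos} positives / {n_neg} negatives")

over = smote_oversample(fm, ResampleConfig(method="smote", k_neighbors=5, seed=42))
print(f"SMOTE:  {(over.labels == 1).sum()} positives / {(over.labels == 0).sum()} negatives "
      f"({over.n_samples - fm.n_samples} synthetic rows, ids flagged '__smote')")

under = random_undersample(fm, ResampleConfig(method="random_under", seed=42))
print(f"under:  {(under.labels == 1).sum()} positives / {(under.labels == 0).sum()} negatives")

synth = over.values[fm.n_samples:]
minority = fm.values[fm.labels == 1]
inside = ((synth >= minority.min(0)) & (synth <= minority.max(0))).all()
print(f"\nevery synthetic point lies inside the minority bounding box: {inside}")
print("(SMOTE interpolates between a minority sample and one of its k nearest")
print("minority neighbours, so synthetic rows can never leave the class hull)")
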