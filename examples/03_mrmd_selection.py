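"""Rank features by MRMD and pick a subset by forward selection.

Plants 3 weakly informative features among 17 noise features; the MRMD
score (|Pearson correlation with the label| + mean Euclidean distance
to the other features) ranks them, and incremental selection walks the
ranking, cross-validating a random forest at each subset size.
"""

import numpy as np

from antioxseq import FeatureMatrix, incremental_select, mrmd_rank

rng = np.random.default_rng(7)
n = 120
labels = np.array([1, 0] * (n // 2))
planted = 0.9 * labels[:, None] + rng.normal(size=(n, 3))
noise = rng.normal(size=(n, 17))
fm = FeatureMatrix(
    [f"s{i}" for i in range(n)],
    [f"signal{j}" for j in range(3)] + [f"noise{j}" for j in range(17)],
    np.hstack([planted, noise]),
    labels,
)

table = mrmd_rank(fm)
print("top 5 of the MRMD ranking (score = MR + MD):")
print(table.to_dataframe().sort_values("rank").head(5).to_string(index=False))

sel = incremental_select(fm, table, folds=5, step=1, seed=0, trees=50)
print(f"\naccuracy curve over subset sizes 1..{fm.n_features}:")
for size, acc in zip(sel.sizes[:8], sel.accuracies[:8]):
    print(f"  size {size:2d}: CV accuracy {acc:.3f}")
print(f"\nchosen: {sel.chosen_size} features at accuracy {sel.chosen_accuracy:.3f}")
print(f"planted features recovered: {sorted(f for f in sel.chosen_features if f.startswith('signal'))}")
print("\n(the rule keeps the smallest subset attaining the maximal accuracy,")
print("so noise features are only admitted if they genuinely help)")
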