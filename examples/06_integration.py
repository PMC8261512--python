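"""Stack four platform scores with a Bernoulli naive-Bayes integrator.

Each platform's probability score is binarized at its own optimized cutoff
and the four votes are combined by Bayes' rule with Laplace smoothing.
With complementary platform signals the integrated score tracks or beats
the best single platform.
"""

import numpy as np
from sklearn.model_selection import StratifiedKFold

from noduleomics import (generate_platform_scores, platform_importance,
                         predict_integrated, rank_auc, train_integrator)

scores, labels = generate_platform_scores(seed=0)
y = (labels == "malignant").astype(int).to_numpy()

for col in scores.columns:
    print(f"{col:20s} AUC = {rank_auc(scores[col], y):.3f}")

oof = np.full(len(y), np.nan)
for tr, te in StratifiedKFold(13, shuffle=True, random_state=0).split(scores, y):
    params = train_integrator(scores.iloc[tr], labels.iloc[tr])
    oof[te] = predict_integrated(params, scores.iloc[te])
print(f"{'integrated (OOF)':20s} AUC = {rank_auc(oof, y):.3f}")

params = train_integrator(scores, labels)
weights = platform_importance(params, scores, labels)
print("importance weights:",
      {k: round(v, 3) for k, v in weights.items()})
print("weights are the mean posterior each platform alone assigns to the")
print("true class: 0.5 = uninformative, 1 = perfectly informative")
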