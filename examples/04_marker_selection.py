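"""Consensus univariate screening of serum markers and age.

Six tests per feature (ANOVA, Fisher, chi-square, Wilcoxon, Mann-Whitney,
Student's t); a feature is a candidate marker when p < 0.1 in at least
four of them. The univariate AUC is reported for reference only.
"""

from noduleomics import CohortSpec, generate_clinical, generate_proteins
from noduleomics.selection import results_frame, screen_features

spec = CohortSpec.default(seed=0)
clinical, labels = generate_clinical(spec)
table = generate_proteins(spec)
table["age"] = clinical["age"]

results = screen_features(table, labels)
frame = results_frame(results)
print(frame[["n_passed", "selected", "auc"]].round(3).to_string())
print("\nselected:", [r.feature for r in results if r.selected])
print("the three shifted markers (CEA, CYFRA 21-1, SCC) and age pass the")
print("4-of-6 consensus; the unshifted markers do not")
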