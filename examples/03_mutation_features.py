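"""Classify somatic calls into functional levels and build the 8 features.

Level 1: oncogene hotspot variants. Level 2: tumor-suppressor hotspot or
otherwise deleterious variants. Level 3: remaining exonic nonsynonymous.
Level 4: everything else. Each sample becomes (count, max VAF) per level.
"""

from noduleomics import (CohortSpec, classify_mutation_levels,
                         generate_mutations, mutation_feature_matrix)

spec = CohortSpec.default(seed=0)
calls = generate_mutations(spec)
levels = classify_mutation_levels(calls)
print("calls per level across the cohort:",
      levels.value_counts().sort_index().to_dict())

features = mutation_feature_matrix(calls, sample_ids=spec.sample_ids())
sid = features.index[0]
print(f"sample {sid}: " + ", ".join(
    f"{c}={features.loc[sid, c]:.3g}" for c in features.columns))
print("counts say how many calls landed in each level; maxvaf is the")
print("strongest variant signal there (0 = no call at that level)")
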