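"""Cross-dataset consensus: genes co-clustered in every dataset.

Module ids from independent clusterings are not comparable, so consensus is
formed by intersecting co-membership gene pairs across datasets and taking
connected components; the surviving groups are the candidate biomarkers,
whose somatic mutation status is then profiled.
"""

import numpy as np

from netomics import (co_membership_pairs, consensus_groups, generate_annotation,
                      generate_cohort, mutation_profile)
from netomics.communities import Partition
from netomics.synthetic import default_cohort_config

# eight simulated datasets that agree on two modules but disagree on the rest
rng = np.random.default_rng(0)
genes = [f"G{i:04d}" for i in range(30)]
universe = set(genes)
pair_sets = []
for _ in range(8):
    assignment = {g: int(rng.integers(10, 15)) for g in genes}
    for i, g in enumerate(genes[:6]):
        assignment[g] = 0        # stable module A
    for g in genes[6:10]:
        assignment[g] = 1        # stable module B
    pair_sets.append(co_membership_pairs(Partition("louvain", assignment), universe))

groups, singletons = consensus_groups(pair_sets, "hypo")
print(f"consensus groups: {[sorted(g.genes) for g in groups]}")
print(f"singleton survivors (reported, not grouped): {len(singletons)}")

# mutation profile of the consensus genes on a generated cohort
ann, man = generate_annotation(1000, 2000, seed=1)
cohort, truth = generate_cohort(default_cohort_config(seed=1), ann, man, "BRCA")
biomarkers = set().union(*(g.genes for g in groups))
clin = cohort.clinical[cohort.group == "tumor"]
prof = mutation_profile(cohort.mutations, biomarkers, clin)
top = prof.sort_values("n_patients_mutated", ascending=False).head(3)
print("\nmost mutated consensus genes (fraction of mutated patients):")
print(top[["n_patients_mutated", "normalized_fraction"]].round(3))
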