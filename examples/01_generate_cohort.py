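"""Generate a synthetic tumor/normal multi-omics cohort with planted truth.

The generator draws RNA-seq counts (negative binomial), methylation betas
(logistic-normal with planted hypo/hyper shifts), somatic mutations and a
clinical table whose survival times depend on the planted prognostic genes.
"""

import numpy as np

from netomics import generate_annotation, generate_cohort, split_cohort
from netomics.synthetic import chi_square_comparability, default_cohort_config

ann, man = generate_annotation(n_genes=1000, n_probes=2000, seed=1)
cohort, truth = generate_cohort(default_cohort_config(seed=1), ann, man, "BRCA")

print(f"samples: {len(cohort.samples)} "
      f"({(cohort.group == 'tumor').sum()} tumor / {(cohort.group == 'normal').sum()} normal)")
print(f"planted DE genes: {len(truth.de_genes)}, "
      f"planted DM probes: {len(truth.dm_probes_hypo)} hypo / {len(truth.dm_probes_hyper)} hyper")
print(f"planted modules: { {m: len(g) for m, g in truth.module_genes.items()} }")

tum = (cohort.group == "tumor").values
b = cohort.betas.loc[list(truth.dm_probes_hypo)]
delta = (b.values[:, tum].mean(1) - b.values[:, ~tum].mean(1)).mean()
print(f"realized mean delta-beta of planted hypo probes: {delta:.3f} "
      "(negative = less methylated in tumors, as planted)")

train, val = split_cohort(cohort, 0.5, seed=1)
stat, p = chi_square_comparability(train.clinical, val.clinical, "stage")
print(f"train/validation stage comparability: chi-square {stat:.2f}, p {p:.3f} "
      "(large p = the random split is clinically balanced)")
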