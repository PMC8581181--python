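#!/usr/bin/env python
"""Generate the synthetic study cohort.

Writes the seeded default cohort — 300 subjects, 300 mRNAs, 60 miRNAs, two
planted phenotype-linked modules — to results/cohort/ as TSV/JSON and
prints what was planted.
"""

from phenonet.pipeline import stage_seed
from phenonet.synthetic import SimulationConfig, generate_cohort, write_cohort

SEED = 1

config = SimulationConfig(seed=stage_seed(SEED, "simulate"))
mrna, mirna, cov, phenotype, truth = generate_cohort(config)
write_cohort("results/cohort", mrna, mirna, cov, phenotype, truth)

planted = [f for f, m in truth.module_membership.items() if m != "background"]
outliers = int((mirna.to_numpy() > 5_000_000).any(axis=1).sum())
print(f"cohort: {mrna.shape[1]} subjects, {len(mrna)} mRNAs, {len(mirna)} miRNAs")
print(f"planted: {len(planted)} features across {config.n_modules} modules "
      f"({config.module_sizes}), {len(truth.planted_pairs)} miRNA->mRNA pairs")
print(f"hemolysis-like outlier miRNAs (>5M reads in one sample): {outliers}")
print("written to results/cohort/")
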