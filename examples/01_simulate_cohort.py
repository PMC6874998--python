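"""Simulate a synthetic gastric-cancer cohort and summarize its landscape.

Builds the default 74-sample cohort (median nonsilent burden 66 before the
age effect, C>T-dominant spectrum, hotspot drivers, TP53 exclusivity
structure) and prints the tabulations behind a mutation-landscape figure.
"""

from neocohort.simulate import simulate_cohort, study_config, study_proteome
from neocohort.variants import summarize_landscape

proteome = study_proteome(seed=1)
config = study_config(proteome, n_samples=74, seed=1)
mutations, metadata, genotypes = simulate_cohort(proteome, config)

summary = summarize_landscape(mutations)
print(f"samples: {config.n_samples}, mutations: {len(mutations)}")
print(f"median nonsilent burden: {summary.per_sample_nonsilent.median():.0f}")
print("\ncounts by classification:")
print(summary.classification_counts.to_string())
print("\ncounts by SNV class (C>T should dominate):")
print(summary.snv_class_counts.to_string())
print("\ntop 10 genes by mutated-sample count:")
for gene, n in summary.top_genes(10):
    print(f"  {gene:10s} {n:3d} samples")

# The burden median sits above the configured 66 because patients aged >=60
# (the cohort majority) carry a 1.5x multiplier, as observed in real cohorts.
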