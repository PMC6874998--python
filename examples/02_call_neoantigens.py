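"""Call neoantigens for one simulated patient, end to end.

Shows the per-stage record flow: common-variant filter, mutant/wild-type
8-11mer enumeration, three-predictor binding scores, and the consensus
criteria (IC50 < 500 nM in >= 2 tools; mutant binds better than wild-type).
"""

from neocohort.binding import predict_bindings
from neocohort.consensus import call_neoantigens
from neocohort.peptides import enumerate_cohort_pairs
from neocohort.simulate import (
    simulate_binding_truth,
    simulate_cohort,
    simulate_population_af,
    study_config,
    study_proteome,
)
from neocohort.variants import filter_common_variants

proteome = study_proteome(seed=2)
config = study_config(proteome, n_samples=1, seed=2)
mutations, _, genotypes = simulate_cohort(proteome, config)
patient = genotypes[0]
print(f"patient {patient.sample_id}: {len(mutations)} somatic mutations, "
      f"HLA {', '.join(patient.alleles)}")

af_table = simulate_population_af(mutations, common_fraction=0.05, seed=2)
kept = filter_common_variants(mutations, af_table)
print(f"after common-variant filter (AF > 0.5% in any database): {len(kept)}")

pairs, report = enumerate_cohort_pairs(kept, proteome.as_dict())
print(f"peptide pairs from {report.n_missense} missense mutations: {len(pairs)} "
      f"(skipped non-missense: {report.skipped_by_class})")

truth = simulate_binding_truth(sorted(config.hla_frequencies), seed=2)
tools = truth.make_tools(3, seed=2)
predictions = predict_bindings(pairs, patient, tools)
calls = call_neoantigens(predictions, pairs, patient)
print(f"predictions: {len(predictions)}; consensus neoantigen calls: {len(calls)}")
print(f"distinct neoantigen peptides: {calls['mt_peptide'].nunique()}")
if len(calls):
    best = calls.nsmallest(3, "consensus_mt_ic50")
    print("\nstrongest calls (consensus IC50 nM, mutant vs wild-type):")
    for row in best.itertuples(index=False):
        print(f"  {row.mt_peptide} ({row.gene_id} {row.ref_aa}{row.protein_pos}"
              f"{row.alt_aa}, {row.allele}): "
              f"{row.consensus_mt_ic50:.0f} vs {row.consensus_wt_ic50:.0f}")
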