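"""Shared fixtures: tiny deterministic cohorts and helper factories."""

from __future__ import annotations

import pytest

from neocohort.simulate import (
    CohortConfig,
    HLAGenotype,
    ProteomeFixture,
    SMALL_HLA_FREQUENCIES,
    simulate_binding_truth,
    simulate_cohort,
    study_config,
    study_proteome,
)
from neocohort.variants import SomaticMutation


def make_missense(
    sample_id="S0001",
    gene_id="GENE0001",
    protein_pos=5,
    ref_aa="A",
    alt_aa="G",
    chrom="chr1",
    genomic_pos=1000,
    ref_allele="C",
    alt_allele="T",
) -> SomaticMutation:
    return SomaticMutation(
        sample_id=sample_id,
        gene_id=gene_id,
        chrom=chrom,
        genomic_pos=genomic_pos,
        ref_allele=ref_allele,
        alt_allele=alt_allele,
        variant_type="SNP",
        variant_classification="missense",
        protein_pos=protein_pos,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
    )


@pytest.fixture(scope="session")
def small_proteome() -> ProteomeFixture:
    return ProteomeFixture(
        records=(
            ("GENE0001", "ACDEFGHIKLMNPQRSTVWY" * 3),  # 60 aa
            ("GENE0002", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"),  # 33 aa
        )
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """A 12-sample simulated cohort with default structure, small burden."""
    proteome = study_proteome(seed=11)
    config = study_config(
        proteome,
        n_samples=12,
        seed=11,
        burden_median=10.0,
        hla_frequencies=dict(SMALL_HLA_FREQUENCIES),
    )
    mutations, metas, genotypes = simulate_cohort(proteome, config)
    truth = simulate_binding_truth(sorted(config.hla_frequencies), seed=11)
    return proteome, config, mutations, metas, genotypes, truth


@pytest.fixture()
def single_genotype() -> HLAGenotype:
    return HLAGenotype(sample_id="S0001", alleles=("HLA-A11:01", "HLA-B40:01"))
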