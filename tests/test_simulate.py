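"""Synthetic-cohort generator: determinism, calibration and structure."""

import numpy as np
import pytest
from scipy import stats as sps

from neocohort.errors import ConsistencyError, ParameterError
from neocohort.simulate import (
    CohortConfig,
    SMALL_HLA_FREQUENCIES,
    designed_binder_truth,
    force_residues,
    simulate_binding_truth,
    simulate_cohort,
    simulate_population_af,
    simulate_proteome,
    study_config,
    study_proteome,
)
from neocohort.variants import NONSILENT_CLASSES


def small_config(**overrides):
    params = dict(
        n_samples=10,
        burden_median=8.0,
        hotspots=(),
        exclusive_pairs=(),
        age_effect=1.0,
        hla_frequencies=dict(SMALL_HLA_FREQUENCIES),
        seed=1,
    )
    params.update(overrides)
    return CohortConfig(**params)


class TestProteome:
    def test_forced_single_gene_length(self):
        proteome = simulate_proteome(1, 8, 8, seed=1)
        assert len(proteome.records) == 1
        assert len(proteome.records[0][1]) == 8

    def test_determinism(self):
        a = simulate_proteome(50, 100, 500, seed=7)
        b = simulate_proteome(50, 100, 500, seed=7)
        assert a.records == b.records

    def test_residue_frequencies_uniform(self):
        proteome = simulate_proteome(200, 100, 100, seed=3)
        residues = "".join(seq for _, seq in proteome.records)
        n = len(residues)
        # each residue count within 5 SE of n/20
        se = np.sqrt(n * (1 / 20) * (19 / 20))
        for aa in "ACDEFGHIKLMNPQRSTVWY":
            assert abs(residues.count(aa) - n / 20) < 5 * se

    def test_invalid_bounds_raise(self):
        with pytest.raises(ParameterError):
            simulate_proteome(5, 4, 10, seed=1)
        with pytest.raises(ParameterError):
            simulate_proteome(0, 8, 10, seed=1)


class TestCohort:
    def test_prevalence_one_hotspot_in_every_sample(self):
        proteome = simulate_proteome(3, 50, 50, seed=2)
        gene, seq = proteome.records[0]
        ref = seq[9]
        alt = "A" if ref != "A" else "C"
        config = small_config(hotspots=((gene, 10, ref, alt, 1.0),))
        mutations, metas, _ = simulate_cohort(proteome, config)
        carriers = {
            m.sample_id for m in mutations
            if m.gene_id == gene and m.protein_pos == 10 and m.alt_aa == alt
        }
        assert carriers == {m.sample_id for m in metas}

    def test_hotspot_prevalence_within_binomial_interval(self):
        proteome = simulate_proteome(3, 50, 50, seed=2)
        gene, seq = proteome.records[0]
        ref = seq[9]
        alt = "A" if ref != "A" else "C"
        config = small_config(
            n_samples=1000, burden_median=5.0, hotspots=((gene, 10, ref, alt, 0.1),)
        )
        mutations, _, _ = simulate_cohort(proteome, config)
        carriers = len({
            m.sample_id for m in mutations
            if m.gene_id == gene and m.protein_pos == 10 and m.alt_aa == alt
        })
        lo, hi = sps.binom.ppf([0.005, 0.995], 1000, 0.1)
        assert lo <= carriers <= hi

    def test_age_effect_raises_old_group_burden(self):
        proteome = simulate_proteome(5, 200, 400, seed=4)
        config = small_config(n_samples=1000, burden_median=20.0, age_effect=1.5)
        mutations, metas, _ = simulate_cohort(proteome, config)
        burden = {m.sample_id: 0 for m in metas}
        for m in mutations:
            if m.variant_classification in NONSILENT_CLASSES:
                burden[m.sample_id] += 1
        old = [burden[m.sample_id] for m in metas if m.age >= 60]
        young = [burden[m.sample_id] for m in metas if m.age < 60]
        assert np.mean(old) > np.mean(young)

    def test_median_burden_calibration(self):
        proteome = simulate_proteome(5, 300, 600, seed=5)
        config = small_config(n_samples=500, burden_median=66.0, age_effect=1.0)
        mutations, metas, _ = simulate_cohort(proteome, config)
        burden = {m.sample_id: 0 for m in metas}
        for m in mutations:
            if m.variant_classification in NONSILENT_CLASSES:
                burden[m.sample_id] += 1
        values = np.sort(np.array(list(burden.values())))
        # exact binomial order-statistic 99% CI for the population median
        lo_idx = int(sps.binom.ppf(0.005, 500, 0.5))
        hi_idx = int(sps.binom.ppf(0.995, 500, 0.5))
        assert values[lo_idx] <= 66 <= values[hi_idx]

    def test_exclusive_pair_realized_odds_ratio_below_one(self):
        proteome = simulate_proteome(4, 100, 100, seed=6)
        (ga, sa), (gb, sb) = proteome.records[0], proteome.records[1]
        hotspots = (
            (ga, 10, sa[9], "A" if sa[9] != "A" else "C", 0.5),
            (gb, 10, sb[9], "A" if sb[9] != "A" else "C", 0.5),
        )
        config = small_config(
            n_samples=1000, burden_median=3.0,
            hotspots=hotspots, exclusive_pairs=((ga, gb, 0.1),),
        )
        mutations, metas, _ = simulate_cohort(proteome, config)
        has = {g: set() for g in (ga, gb)}
        for m in mutations:
            if m.gene_id in has and m.is_nonsilent:
                has[m.gene_id].add(m.sample_id)
        samples = {m.sample_id for m in metas}
        a = len(has[ga] & has[gb])
        b = len(has[ga] - has[gb])
        c = len(has[gb] - has[ga])
        d = len(samples - has[ga] - has[gb])
        assert (a * d) / (b * c) < 1.0

    def test_mutations_consistent_with_proteome(self, tiny_cohort):
        proteome, _, mutations, _, _, _ = tiny_cohort
        seqs = proteome.as_dict()
        for m in mutations:
            if m.protein_pos is not None and m.variant_classification == "missense":
                assert seqs[m.gene_id][m.protein_pos - 1] == m.ref_aa

    def test_determinism_byte_identical(self):
        proteome = study_proteome(seed=9)
        config = study_config(proteome, n_samples=8, seed=9, burden_median=6.0,
                              hla_frequencies=dict(SMALL_HLA_FREQUENCIES))
        out1 = simulate_cohort(proteome, config)
        out2 = simulate_cohort(proteome, config)
        assert out1 == out2

    def test_hotspot_reference_mismatch_raises(self):
        proteome = simulate_proteome(2, 50, 50, seed=2)
        gene, seq = proteome.records[0]
        wrong = "A" if seq[9] == "C" else "C"
        config = small_config(hotspots=((gene, 10, wrong, "G", 0.5),))
        with pytest.raises(ConsistencyError):
            simulate_cohort(proteome, config)

    def test_genotypes_have_one_to_six_wellformed_alleles(self, tiny_cohort):
        _, _, _, _, genotypes, _ = tiny_cohort
        import re

        for g in genotypes:
            assert 1 <= len(g.alleles) <= 6
            assert len(set(g.alleles)) == len(g.alleles)
            for allele in g.alleles:
                assert re.match(r"^HLA-[ABC]\d{2}:\d{2}$", allele)

    def test_hla_frequencies_must_sum_to_one_per_locus(self):
        with pytest.raises(ParameterError, match="locus"):
            small_config(hla_frequencies={"HLA-A11:01": 0.7, "HLA-A24:02": 0.2,
                                          "HLA-B40:01": 1.0, "HLA-C07:02": 1.0})


class TestPopulationAF:
    def _mutations(self):
        proteome = simulate_proteome(4, 200, 300, seed=8)
        config = small_config(n_samples=30, burden_median=15.0)
        mutations, _, _ = simulate_cohort(proteome, config)
        return mutations

    def test_zero_fraction_filters_nothing(self):
        from neocohort.variants import filter_common_variants

        mutations = self._mutations()
        table = simulate_population_af(mutations, 0.0, seed=1)
        assert filter_common_variants(mutations, table) == mutations

    def test_full_fraction_filters_everything(self):
        from neocohort.variants import filter_common_variants

        mutations = self._mutations()
        table = simulate_population_af(mutations, 1.0, seed=1)
        assert filter_common_variants(mutations, table) == []

    def test_reproducible_flag_count(self):
        mutations = self._mutations()
        t1 = simulate_population_af(mutations, 0.2, seed=42)
        t2 = simulate_population_af(mutations, 0.2, seed=42)
        assert t1.frame.equals(t2.frame)
        n_distinct = len({m.variant_key for m in mutations})
        flagged = sum(t1.is_common(k) for k in {m.variant_key for m in mutations})
        assert flagged == round(0.2 * n_distinct)


class TestBindingTruth:
    def test_zero_motif_strength_flattens_scores(self):
        truth = simulate_binding_truth(["HLA-A11:01"], motif_strength=0.0,
                                       noise_sd=0.0, seed=1)
        pssm = truth.pssms[("HLA-A11:01", 9)]
        assert np.allclose(pssm.weights, pssm.weights[0, 0])
        assert truth.truth_score("ACDEFGHIK", "HLA-A11:01") == pytest.approx(
            truth.truth_score("WWWWWWWWW", "HLA-A11:01")
        )

    def test_every_allele_and_length_covered(self):
        alleles = ["HLA-A11:01", "HLA-B40:01", "HLA-C07:02"]
        truth = simulate_binding_truth(alleles, seed=2)
        assert set(truth.pssms) == {(a, L) for a in alleles for L in (8, 9, 10, 11)}

    def test_designed_truth_guarantees_mutant_advantage(self):
        truth = designed_binder_truth(["HLA-A11:01"], penalized_aa="R")
        pssm = truth.pssms[("HLA-A11:01", 9)]
        wt = "ACDRFGHIK"  # contains the penalized residue
        mt = "ACDQFGHIK"
        assert truth.truth_score(mt, "HLA-A11:01") > truth.truth_score(wt, "HLA-A11:01")
        from neocohort.binding import score_to_ic50

        # even an all-penalized peptide stays below the 500 nM threshold
        assert score_to_ic50(truth.truth_score("R" * 9, "HLA-A11:01")) < 500


class TestForceResidues:
    def test_residue_pinned(self):
        proteome = simulate_proteome(1, 20, 20, seed=1)
        gene = proteome.records[0][0]
        forced = force_residues(proteome, [(gene, 5, "W")])
        assert forced.as_dict()[gene][4] == "W"
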