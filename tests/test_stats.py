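"""Cohort statistics: exact tests vs enumeration oracles, recurrence,
panel selection and subgroup comparisons."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from neocohort.errors import (
    ParameterError,
    ReconciliationError,
    StratificationError,
    UndefinedCorrelationError,
)
from neocohort.stats import (
    SubgroupComparison,
    benjamini_hochberg,
    compare_subgroups,
    fisher_exact_2x2,
    mutual_exclusivity_screen,
    neoantigen_load,
    panel_coverage,
    recurrent_neoantigens,
    select_panel_greedy,
    spearman_rho,
    wilcoxon_rank_sum,
)

from conftest import make_missense


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (
            math.comb(col1, x)
            * math.comb(n - col1, row1 - x)
            / math.comb(n, row1)
        )

    observed = prob(a)
    total = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p = prob(x)
        if p <= observed * (1 + 1e-12):
            total += p
    return min(total, 1.0)


def wilcoxon_oracle(x, y):
    """Exact two-sided rank-sum p by enumeration of all group assignments."""
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}  # tie-free data only
    observed = sum(ranks[v] for v in x)
    n = len(pooled)
    stats = [
        sum(ranks[pooled[i]] for i in combo)
        for combo in itertools.combinations(range(n), len(x))
    ]
    mean = np.mean(stats)
    extreme = sum(1 for s in stats if abs(s - mean) >= abs(observed - mean) - 1e-12)
    return extreme / len(stats)


class TestFisherExact:
    def test_diagonal_table(self):
        assert fisher_exact_2x2([[2, 0], [0, 2]]).p_value == pytest.approx(1 / 3)

    def test_balanced_table_p_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    def test_row_swap_symmetry(self):
        for table in ([[3, 1], [2, 5]], [[0, 4], [6, 1]], [[2, 2], [3, 0]]):
            swapped = [table[1], table[0]]
            assert fisher_exact_2x2(table).p_value == pytest.approx(
                fisher_exact_2x2(swapped).p_value
            )

    def test_matches_enumeration_for_small_tables(self):
        # spot-check here; the exhaustive sweep lives in the acceptance suite
        for a, b, c, d in [(2, 3, 1, 4), (0, 5, 5, 0), (3, 0, 2, 2), (1, 1, 1, 1)]:
            assert fisher_exact_2x2([[a, b], [c, d]]).p_value == pytest.approx(
                fisher_oracle(a, b, c, d), abs=1e-12
            )

    def test_negative_entry_rejected(self):
        with pytest.raises(ParameterError):
            fisher_exact_2x2([[1, -1], [0, 2]])

    def test_odds_ratio_is_sample_odds_ratio(self):
        res = fisher_exact_2x2([[4, 2], [1, 3]])
        assert res.statistic == pytest.approx(6.0)


class TestWilcoxon:
    def test_extreme_split_exact_p(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.exact
        assert res.p_value == pytest.approx(1 / 3)

    def test_identical_multisets_p_one(self):
        res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for nx in (2, 3, 4):
            for ny in (2, 3):
                data = rng.permutation(np.arange(1, nx + ny + 1))
                x, y = list(data[:nx]), list(data[nx:])
                assert wilcoxon_rank_sum(x, y).p_value == pytest.approx(
                    wilcoxon_oracle(x, y), abs=1e-12
                )

    def test_large_or_tied_samples_use_approximation(self):
        res = wilcoxon_rank_sum(list(range(15)), list(range(15)))
        assert not res.exact

    def test_empty_group_rejected(self):
        with pytest.raises(ParameterError):
            wilcoxon_rank_sum([], [1.0])


class TestSpearman:
    def test_perfect_inverse(self):
        assert spearman_rho([1, 2, 3], [3, 2, 1]).statistic == pytest.approx(-1.0)

    def test_monotone_transform_gives_one(self):
        x = [1.0, 2.5, 4.0, 7.0, 11.0]
        y = [math.exp(v) for v in x]
        assert spearman_rho(x, y).statistic == pytest.approx(1.0)

    def test_matches_rank_then_pearson(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=10), rng.normal(size=10)
        rx = pd.Series(x).rank().to_numpy()
        ry = pd.Series(y).rank().to_numpy()
        manual = np.corrcoef(rx, ry)[0, 1]
        assert spearman_rho(x, y).statistic == pytest.approx(manual, abs=1e-12)

    def test_zero_rank_variance_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman_rho([1, 1, 1], [1, 2, 3])


# ---------------------------------------------------------------------------
# load, recurrence, panels
# ---------------------------------------------------------------------------

def calls_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["sample_id", "gene_id", "protein_pos", "ref_aa", "alt_aa",
                 "length", "start", "mut_offset", "mt_peptide", "wt_peptide", "allele"],
    )


def meta_frame(sample_ids, ages=None):
    ages = ages or [50] * len(sample_ids)
    return pd.DataFrame({
        "sample_id": sample_ids, "age": ages,
        "sex": ["male"] * len(sample_ids), "lauren": ["NA"] * len(sample_ids),
        "stage": ["NA"] * len(sample_ids), "location": ["NA"] * len(sample_ids),
    })


class TestLoad:
    def test_windows_sharing_peptide_count_once(self):
        calls = calls_frame([
            ("S1", "G", 5, "A", "V", 9, s, 5, "PEPTIDEKK", "PAPTIDEKK", "HLA-A11:01")
            for s in (1, 2, 3)
        ])
        muts = [make_missense(sample_id="S1", gene_id="G")]
        loads = neoantigen_load(calls, muts, meta_frame(["S1"]))
        assert loads.loc[0, "n_neoantigens"] == 1

    def test_call_free_sample_zero_filled(self):
        loads = neoantigen_load(calls_frame([]), [], meta_frame(["S1", "S2"]))
        assert list(loads["n_neoantigens"]) == [0, 0]
        assert list(loads["sample_id"]) == ["S1", "S2"]

    def test_counts_match_independent_recount(self, tiny_cohort):
        from neocohort.consensus import predict_and_call
        from neocohort.peptides import enumerate_cohort_pairs

        proteome, _, mutations, metas, genotypes, truth = tiny_cohort
        pairs, _ = enumerate_cohort_pairs(mutations, proteome.as_dict())
        calls = predict_and_call(pairs, genotypes, truth.make_tools(2, seed=11))
        loads = neoantigen_load(calls, mutations, metas)
        recount = calls.groupby("sample_id")["mt_peptide"].nunique()
        for row in loads.itertuples(index=False):
            assert row.n_neoantigens == recount.get(row.sample_id, 0)

    def test_unknown_sample_raises_reconciliation_error(self):
        muts = [make_missense(sample_id="GHOST")]
        with pytest.raises(ReconciliationError, match="GHOST"):
            neoantigen_load(calls_frame([]), muts, meta_frame(["S1"]))

    def test_age_group_dichotomy_at_60(self):
        loads = neoantigen_load(calls_frame([]), [], meta_frame(["S1", "S2"], ages=[59, 60]))
        assert list(loads["age_group"]) == ["lt60", "ge60"]


class TestRecurrence:
    def test_singleton_excluded_at_min_two(self):
        calls = calls_frame([
            ("S1", "G", 5, "A", "V", 9, 1, 5, "AAAAAAAAA", "AAAAVAAAA", "HLA-A11:01"),
        ])
        assert recurrent_neoantigens(calls, min_samples=2).empty

    def test_min_one_returns_all_identities(self):
        calls = calls_frame([
            ("S1", "G", 5, "A", "V", 9, 1, 5, "PEP1AAAAA", "XEP1AAAAA", "HLA-A11:01"),
            ("S2", "G", 5, "A", "V", 9, 1, 5, "PEP2AAAAA", "XEP2AAAAA", "HLA-A11:01"),
        ])
        table = recurrent_neoantigens(calls, min_samples=1)
        assert set(table["identity"]) == {"PEP1AAAAA", "PEP2AAAAA"}

    def test_peptide_vs_peptide_allele_identity(self):
        calls = calls_frame([
            ("S1", "G", 5, "A", "V", 9, 1, 5, "SAMEPEPTI", "XAMEPEPTI", "HLA-A11:01"),
            ("S2", "G", 5, "A", "V", 9, 1, 5, "SAMEPEPTI", "XAMEPEPTI", "HLA-B40:01"),
        ])
        assert len(recurrent_neoantigens(calls, min_samples=2)) == 1
        assert recurrent_neoantigens(calls, min_samples=2, identity="peptide_allele").empty

    def test_sorted_by_count_then_identity(self):
        rows = []
        for s in ("S1", "S2", "S3"):
            rows.append((s, "G", 5, "A", "V", 9, 1, 5, "BIGPEPTID", "XIGPEPTID", "HLA-A11:01"))
        for s in ("S1", "S2"):
            rows.append((s, "G", 9, "C", "W", 9, 1, 5, "AAAPEPTID", "XAAPEPTID", "HLA-A11:01"))
            rows.append((s, "G", 9, "C", "W", 9, 1, 5, "ZZZPEPTID", "XZZPEPTID", "HLA-A11:01"))
        table = recurrent_neoantigens(calls_frame(rows))
        assert list(table["identity"]) == ["BIGPEPTID", "AAAPEPTID", "ZZZPEPTID"]


class TestPanel:
    def toy_recurrence(self):
        return pd.DataFrame({
            "identity": ["P1", "P2", "P3"],
            "carriers": [["S1", "S2"], ["S2", "S3"], ["S4"]],
            "n_samples": [2, 2, 1],
        })

    def toy_calls(self):
        rows = []
        for pep, samples in (("P1", ["S1", "S2"]), ("P2", ["S2", "S3"]), ("P3", ["S4"])):
            for s in samples:
                rows.append((s, "G", 5, "A", "V", 9, 1, 5, pep, "W" + pep[1:], "HLA-A11:01"))
        return calls_frame(rows)

    def test_hand_enumerated_greedy_trace(self):
        panel = select_panel_greedy(self.toy_recurrence(), k=2)
        # P1 first (2 new), then P2 wins the 1-new tie on total carrier count
        assert panel == ["P1", "P2"]
        coverage = panel_coverage(self.toy_calls(), panel, ["S1", "S2", "S3", "S4"])
        assert coverage == pytest.approx(0.75)

    def test_k_one_picks_largest_carrier_set(self):
        assert select_panel_greedy(self.toy_recurrence(), k=1) == ["P1"]

    def test_large_k_stops_at_zero_marginal_gain(self):
        panel = select_panel_greedy(self.toy_recurrence(), k=10)
        assert panel == ["P1", "P2", "P3"]

    def test_empty_panel_zero_coverage(self):
        assert panel_coverage(self.toy_calls(), [], ["S1", "S2"]) == 0.0

    def test_full_panel_covers_all_called_samples(self):
        calls = self.toy_calls()
        coverage = panel_coverage(calls, ["P1", "P2", "P3"], ["S1", "S2", "S3", "S4", "S5"])
        assert coverage == pytest.approx(4 / 5)

    def test_coverage_monotone_in_panel_growth(self):
        calls = self.toy_calls()
        cohort = ["S1", "S2", "S3", "S4"]
        panel = select_panel_greedy(self.toy_recurrence(), k=3)
        values = [panel_coverage(calls, panel[:i], cohort) for i in range(4)]
        assert values == sorted(values)
        assert values[-1] >= panel_coverage(calls, [panel[0]], cohort)


class TestExclusivity:
    def test_perfectly_exclusive_pair(self):
        matrix = pd.DataFrame(
            [[1] * 10 + [0] * 10, [0] * 10 + [1] * 10],
            index=["A", "B"], columns=[f"S{i}" for i in range(20)],
        )
        (result,) = mutual_exclusivity_screen(matrix)
        assert result.direction == "exclusive"
        assert result.table == ((0, 10), (10, 0))
        assert result.test.p_value == pytest.approx(fisher_oracle(0, 10, 10, 0), abs=1e-12)

    def test_all_zero_gene_row_undetermined(self):
        matrix = pd.DataFrame(
            [[1, 0, 1, 0], [0, 0, 0, 0]], index=["A", "B"],
            columns=["S1", "S2", "S3", "S4"],
        )
        (result,) = mutual_exclusivity_screen(matrix)
        assert result.direction == "undetermined"
        assert result.test.p_value == 1.0

    def test_bh_correction_appends_monotone_q(self):
        rng = np.random.default_rng(2)
        matrix = pd.DataFrame(
            rng.integers(0, 2, size=(6, 40)),
            index=[f"G{i}" for i in range(6)],
            columns=[f"S{i}" for i in range(40)],
        )
        results = mutual_exclusivity_screen(matrix, correction="benjamini_hochberg")
        qs = np.array([r.q_value for r in results])
        ps = np.array([r.test.p_value for r in results])
        assert np.all(qs >= ps - 1e-12)
        assert np.all(qs <= 1.0)
        np.testing.assert_allclose(qs, benjamini_hochberg(ps))

    def test_missing_gene_raises(self):
        matrix = pd.DataFrame([[1, 0]], index=["A"], columns=["S1", "S2"])
        with pytest.raises(ParameterError, match="absent"):
            mutual_exclusivity_screen(matrix, gene_pairs=[("A", "Z")])


class TestSubgroups:
    def load_table(self, values_by_level, stratifier="sex"):
        rows = []
        i = 0
        for level, values in values_by_level.items():
            for v in values:
                i += 1
                rows.append({"sample_id": f"S{i}", "n_nonsilent": 1,
                             "n_neoantigens": v, "age": 50, "age_group": "lt60",
                             "sex": "male", "lauren": "NA", "stage": "NA",
                             "location": "NA"})
                rows[-1][stratifier] = level
        return pd.DataFrame(rows)

    def test_identical_groups_p_one(self):
        loads = self.load_table({"male": [1, 2, 3], "female": [1, 2, 3]})
        (res,) = compare_subgroups(loads, "sex")
        assert res.test.p_value == pytest.approx(1.0)

    def test_four_levels_give_six_pairwise_tests(self):
        loads = self.load_table(
            {"I": [1, 2], "II": [2, 3], "III": [3, 4], "IV": [4, 5]}, stratifier="stage"
        )
        results = compare_subgroups(loads, "stage")
        assert len(results) == 6
        assert all(isinstance(r, SubgroupComparison) for r in results)

    def test_na_level_excluded_and_counted(self):
        loads = self.load_table({"male": [1, 2], "female": [3, 4], "NA": [9]})
        (res,) = compare_subgroups(loads, "sex")
        assert res.n_na_excluded == 1

    def test_single_usable_level_raises(self):
        loads = self.load_table({"male": [1, 2], "NA": [3]})
        with pytest.raises(StratificationError):
            compare_subgroups(loads, "sex")
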