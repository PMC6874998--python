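"""Cohort-level neoantigen statistics.

Per-sample load, recurrent ("public") neoantigen tables, greedy
maximum-coverage panel selection, mutual-exclusivity screening and subgroup
comparisons.  The hypothesis tests are the field's standard ones — Fisher's
exact test for 2x2 co-mutation tables, the Wilcoxon rank-sum test for load
comparisons, Spearman correlation for load vs burden — computed through
scipy.stats and wrapped in a uniform :class:`TestResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    ParameterError,
    ReconciliationError,
    StratificationError,
    UndefinedCorrelationError,
)
from .variants import NONSILENT_CLASSES, SomaticMutation  # noqa: F401


@dataclass(frozen=True)
class TestResult:
    """A statistic, its p-value and how they were computed."""

    statistic: float
    p_value: float
    method: str                  # fisher_exact | wilcoxon_rank_sum | spearman
    n: tuple
    exact: bool
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ParameterError(f"p-value outside [0, 1]: {self.p_value}")


# ---------------------------------------------------------------------------
# Exact small-sample tests
# ---------------------------------------------------------------------------

def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 count table.

    The p-value sums hypergeometric probabilities (margins fixed) of all
    tables at most as probable as the observed one.  The statistic is the
    sample odds ratio ad/bc (inf or nan when a margin degenerates); a
    Haldane-corrected (+0.5) version is reported in ``extra`` for display.
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ParameterError("table must be 2x2 with nonnegative entries")
    if arr.sum() == 0:
        raise ParameterError("table total must be positive")
    a, b, c, d = arr.ravel()
    _, p = sps.fisher_exact(arr, alternative="two-sided")
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = (a * d) / (b * c)
    odds_display = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return TestResult(
        statistic=float(odds),
        p_value=float(min(p, 1.0)),
        method="fisher_exact",
        n=(int(arr.sum()),),
        exact=True,
        extra={"odds_ratio_haldane": float(odds_display)},
    )


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    ``mode='auto'`` uses the exact null distribution when
    ``n_x + n_y <= 20`` and there are no ties, otherwise the normal
    approximation with tie and continuity corrections.  The statistic is
    the Mann-Whitney U of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("both groups must be non-empty")
    if mode not in ("auto", "exact", "approx"):
        raise ParameterError(f"unknown mode {mode!r}")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    use_exact = mode == "exact" or (
        mode == "auto" and x.size + y.size <= 20 and not has_ties
    )
    if use_exact and has_ties:
        raise ParameterError("exact mode requires tie-free data")
    method = "exact" if use_exact else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="wilcoxon_rank_sum",
        n=(int(x.size), int(y.size)),
        exact=use_exact,
    )


def spearman_rho(x, y) -> TestResult:
    """Spearman rank correlation with the t-distribution p approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ParameterError("x and y must have equal length >= 3")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise UndefinedCorrelationError("zero variance in ranks")
    res = sps.spearmanr(x, y)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="spearman",
        n=(int(x.size),),
        exact=False,
    )


# ---------------------------------------------------------------------------
# Load table
# ---------------------------------------------------------------------------

LOAD_COLUMNS = [
    "sample_id", "n_nonsilent", "n_neoantigens",
    "age", "age_group", "sex", "lauren", "stage", "location",
]


def neoantigen_load(
    calls: pd.DataFrame,
    mutations: Sequence[SomaticMutation],
    metadata,
) -> pd.DataFrame:
    """Per-sample nonsilent burden and neoantigen load joined to metadata.

    The neoantigen count is the number of distinct mutant-peptide strings
    called for the sample (windows and alleles sharing a peptide count
    once).  Samples without calls or without mutations appear with zeros.
    Mutation or call samples unknown to the metadata raise
    :class:`ReconciliationError`.
    """
    meta_frame = _metadata_frame(metadata)
    universe = set(meta_frame["sample_id"])
    mut_samples = {m.sample_id for m in mutations}
    orphans = sorted(mut_samples - universe)
    if orphans:
        raise ReconciliationError(f"mutation samples missing from metadata: {orphans}")
    if len(calls):
        call_orphans = sorted(set(calls["sample_id"]) - universe)
        if call_orphans:
            raise ReconciliationError(f"call samples missing from metadata: {call_orphans}")

    burden = pd.Series(0, index=meta_frame["sample_id"], dtype=int)
    for m in mutations:
        if m.variant_classification in NONSILENT_CLASSES:
            burden[m.sample_id] += 1
    if len(calls):
        neo = calls.groupby("sample_id")["mt_peptide"].nunique()
    else:
        neo = pd.Series(dtype=int)
    table = meta_frame.copy()
    table["n_nonsilent"] = burden.reindex(table["sample_id"]).to_numpy()
    table["n_neoantigens"] = (
        neo.reindex(table["sample_id"]).fillna(0).astype(int).to_numpy()
    )
    table["age_group"] = np.where(table["age"] >= 60, "ge60", "lt60")
    return table[LOAD_COLUMNS].sort_values("sample_id").reset_index(drop=True)


def _metadata_frame(metadata) -> pd.DataFrame:
    if isinstance(metadata, pd.DataFrame):
        return metadata.copy()
    return pd.DataFrame(
        [
            (m.sample_id, m.age, m.sex, m.lauren, m.stage, m.location)
            for m in metadata
        ],
        columns=["sample_id", "age", "sex", "lauren", "stage", "location"],
    )


# ---------------------------------------------------------------------------
# Recurrence and panel coverage
# ---------------------------------------------------------------------------

def recurrent_neoantigens(
    calls: pd.DataFrame,
    min_samples: int = 2,
    identity: str = "peptide",
) -> pd.DataFrame:
    """Neoantigen identities carried by at least ``min_samples`` samples.

    ``identity='peptide'`` counts a mutant peptide shared across samples
    regardless of presenting allele (the convention for "public"
    neoantigens across cohorts with differing HLA); ``'peptide_allele'``
    requires the allele to match too.  Rows sorted by carrier count
    descending, then identity.
    """
    if min_samples < 1:
        raise ParameterError("min_samples must be >= 1")
    if identity not in ("peptide", "peptide_allele"):
        raise ParameterError(f"unknown identity mode {identity!r}")
    if not len(calls):
        return pd.DataFrame(
            columns=["identity", "mt_peptide", "allele", "gene_id", "aa_change",
                     "n_samples", "carriers"]
        )
    work = calls.copy()
    work["aa_change"] = (
        work["ref_aa"].astype(str)
        + work["protein_pos"].astype(int).astype(str)
        + work["alt_aa"].astype(str)
    )
    if identity == "peptide":
        work["identity"] = work["mt_peptide"]
    else:
        work["identity"] = work["mt_peptide"] + "|" + work["allele"]
    grouped = work.groupby("identity").agg(
        mt_peptide=("mt_peptide", "first"),
        allele=("allele", lambda s: ";".join(sorted(set(s)))),
        gene_id=("gene_id", lambda s: ";".join(sorted(set(s)))),
        aa_change=("aa_change", lambda s: ";".join(sorted(set(s)))),
        n_samples=("sample_id", "nunique"),
        carriers=("sample_id", lambda s: sorted(set(s))),
    )
    table = grouped[grouped["n_samples"] >= min_samples].reset_index()
    return (
        table.sort_values(["n_samples", "identity"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )


def select_panel_greedy(recurrence: pd.DataFrame, k: int) -> list[str]:
    """Greedy maximum-coverage panel of neoantigen identities.

    At each step picks the identity covering the most not-yet-covered
    samples; ties broken by larger total carrier count, then lexicographic
    identity.  Stops after ``k`` picks or when nothing adds coverage.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    carrier_sets = {
        row.identity: frozenset(row.carriers) for row in recurrence.itertuples(index=False)
    }
    totals = {i: len(s) for i, s in carrier_sets.items()}
    covered: set[str] = set()
    panel: list[str] = []
    remaining = dict(carrier_sets)
    while len(panel) < k and remaining:
        best = max(
            remaining.items(),
            key=lambda kv: (len(kv[1] - covered), totals[kv[0]], _neg_lex(kv[0])),
        )
        identity, carriers = best
        if not carriers - covered:
            break
        panel.append(identity)
        covered |= carriers
        del remaining[identity]
    return panel


class _neg_lex(str):
    """Inverts lexicographic order so max() prefers the smaller identity."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


def panel_coverage(
    calls: pd.DataFrame,
    panel: Sequence[str],
    cohort_samples: Sequence[str],
    identity: str = "peptide",
) -> float:
    """Fraction of the full cohort carrying >= 1 panel neoantigen."""
    cohort = set(cohort_samples)
    if not cohort:
        raise ParameterError("cohort_samples must be non-empty")
    if not len(calls) or not panel:
        return 0.0
    if identity == "peptide":
        ids = calls["mt_peptide"]
    else:
        ids = calls["mt_peptide"] + "|" + calls["allele"]
    covered = set(calls.loc[ids.isin(set(panel)), "sample_id"]) & cohort
    return len(covered) / len(cohort)


# ---------------------------------------------------------------------------
# Mutual exclusivity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExclusivityResult:
    gene_a: str
    gene_b: str
    table: tuple  # ((both, a_only), (b_only, neither))
    test: TestResult
    direction: str  # exclusive | co_occurring | undetermined
    q_value: Optional[float] = None


def mutual_exclusivity_screen(
    matrix: pd.DataFrame,
    gene_pairs: Optional[Iterable[tuple[str, str]]] = None,
    correction: str = "none",
) -> list[ExclusivityResult]:
    """Fisher-exact screen of gene pairs for exclusivity / co-occurrence.

    ``matrix`` is the binary genes x samples indicator.  For each pair the
    2x2 table (both, A only / B only, neither) is tested; direction is
    ``exclusive`` when the sample odds ratio is < 1, ``co_occurring`` when
    > 1, and ``undetermined`` for degenerate tables (a gene mutated in no
    or all samples), which report p = 1.  ``correction='benjamini_hochberg'``
    appends BH q-values.
    """
    if correction not in ("none", "benjamini_hochberg"):
        raise ParameterError(f"unknown correction {correction!r}")
    values = matrix.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ParameterError("matrix must be binary")
    if gene_pairs is None:
        gene_pairs = combinations(matrix.index, 2)
    results = []
    for gene_a, gene_b in gene_pairs:
        for g in (gene_a, gene_b):
            if g not in matrix.index:
                raise ParameterError(f"gene {g} absent from matrix")
        sa = matrix.loc[gene_a].to_numpy().astype(bool)
        sb = matrix.loc[gene_b].to_numpy().astype(bool)
        a = int(np.sum(sa & sb))
        b = int(np.sum(sa & ~sb))
        c = int(np.sum(~sa & sb))
        d = int(np.sum(~sa & ~sb))
        degenerate = (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0)
        if degenerate:
            test = TestResult(
                statistic=float("nan"), p_value=1.0, method="fisher_exact",
                n=(a + b + c + d,), exact=True,
            )
            direction = "undetermined"
        else:
            test = fisher_exact_2x2([[a, b], [c, d]])
            if np.isnan(test.statistic) or test.statistic == 1.0:
                direction = "undetermined"
            else:
                direction = "exclusive" if test.statistic < 1.0 else "co_occurring"
        results.append(
            ExclusivityResult(
                gene_a=gene_a, gene_b=gene_b,
                table=((a, b), (c, d)), test=test, direction=direction,
            )
        )
    if correction == "benjamini_hochberg" and results:
        qs = benjamini_hochberg([r.test.p_value for r in results])
        results = [
            ExclusivityResult(
                gene_a=r.gene_a, gene_b=r.gene_b, table=r.table,
                test=r.test, direction=r.direction, q_value=float(q),
            )
            for r, q in zip(results, qs)
        ]
    return results


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p, kind="mergesort")
    m = p.size
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# ---------------------------------------------------------------------------
# Subgroup comparisons
# ---------------------------------------------------------------------------

STRATIFIERS = ("age_group", "sex", "lauren", "stage", "location")


@dataclass(frozen=True)
class SubgroupComparison:
    stratifier: str
    level_a: str
    level_b: str
    test: TestResult
    n_na_excluded: int


def compare_subgroups(
    loads: pd.DataFrame,
    stratifier: str,
    value: str = "n_neoantigens",
) -> list[SubgroupComparison]:
    """Wilcoxon comparisons of a load column across the levels of one
    clinical stratifier (all pairwise comparisons for >= 3 levels).

    NA-level samples are excluded and counted.  Raises
    :class:`StratificationError` with < 2 usable levels.
    """
    if stratifier not in loads.columns:
        raise ParameterError(f"unknown stratifier {stratifier!r}")
    labels = loads[stratifier].astype(str)
    usable = loads[labels != "NA"]
    n_na = int((labels == "NA").sum())
    levels = sorted(usable[stratifier].astype(str).unique())
    if len(levels) < 2:
        raise StratificationError(
            f"stratifier {stratifier!r} has {len(levels)} usable level(s)"
        )
    results = []
    for level_a, level_b in combinations(levels, 2):
        x = usable.loc[usable[stratifier].astype(str) == level_a, value].to_numpy()
        y = usable.loc[usable[stratifier].astype(str) == level_b, value].to_numpy()
        results.append(
            SubgroupComparison(
                stratifier=stratifier,
                level_a=level_a,
                level_b=level_b,
                test=wilcoxon_rank_sum(x, y),
                n_na_excluded=n_na,
            )
        )
    return results


# ---------------------------------------------------------------------------
# TSV emitters
# ---------------------------------------------------------------------------

def exclusivity_to_frame(results: Sequence[ExclusivityResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        (a, b), (c, d) = r.table
        row = {
            "gene_a": r.gene_a, "gene_b": r.gene_b,
            "n_both": a, "n_a_only": b, "n_b_only": c, "n_neither": d,
            "odds_ratio": r.test.statistic, "p_value": r.test.p_value,
            "direction": r.direction,
        }
        if r.q_value is not None:
            row["q_value"] = r.q_value
        rows.append(row)
    return pd.DataFrame(rows)


def subgroups_to_frame(results: Sequence[SubgroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "stratifier": r.stratifier,
                "level_a": r.level_a,
                "level_b": r.level_b,
                "n_a": r.test.n[0],
                "n_b": r.test.n[1],
                "statistic": r.test.statistic,
                "p_value": r.test.p_value,
                "mode": "exact" if r.test.exact else "approx",
                "n_na_excluded": r.n_na_excluded,
            }
            for r in results
        ]
    )
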