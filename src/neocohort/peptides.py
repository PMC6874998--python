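"""Mutant/wild-type peptide-pair enumeration.

A missense mutation at protein position ``p`` yields, for each length L in
8-11, every window of the protein that contains ``p``.  The mutant peptide
carries the alternate residue, the wild-type peptide the reference residue,
and the two differ at exactly that one offset.  Only missense variants have
a well-defined single-residue window; other nonsilent classes are counted
and skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence  # noqa: F401

import pandas as pd

from .errors import ConsistencyError, UnsupportedClassificationError
from .variants import SomaticMutation

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_AA)

DEFAULT_LENGTHS = (8, 9, 10, 11)


class PeptidePair(NamedTuple):
    sample_id: str
    gene_id: str
    protein_pos: int  # 1-based residue index of the mutation in the protein
    ref_aa: str
    alt_aa: str
    length: int
    start: int        # 1-based start of the window within the protein
    mut_offset: int   # 1-based position of the mutated residue in the peptide
    mt_peptide: str
    wt_peptide: str


PAIR_COLUMNS = list(PeptidePair._fields)


@dataclass
class EnumerationReport:
    """Bookkeeping for a cohort-level enumeration run."""

    n_missense: int = 0
    n_pairs: int = 0
    skipped_by_class: dict = field(default_factory=dict)
    n_windows_noncanonical: int = 0

    def note_skip(self, classification: str) -> None:
        self.skipped_by_class[classification] = self.skipped_by_class.get(classification, 0) + 1


def apply_missense(protein_seq: str, protein_pos: int, ref_aa: str, alt_aa: str) -> str:
    """Substitute one residue, validating the reference residue first."""
    if not 1 <= protein_pos <= len(protein_seq):
        raise ConsistencyError(
            f"protein position {protein_pos} outside 1..{len(protein_seq)}"
        )
    observed = protein_seq[protein_pos - 1]
    if observed != ref_aa:
        raise ConsistencyError(
            f"reference residue mismatch at position {protein_pos}: "
            f"expected {ref_aa}, protein has {observed}"
        )
    return protein_seq[: protein_pos - 1] + alt_aa + protein_seq[protein_pos:]


def window_count(n: int, p: int, length: int) -> int:
    """Number of length-``length`` windows of an ``n``-residue protein that
    contain position ``p`` (closed form; matches brute-force enumeration)."""
    lo = max(1, p - length + 1)
    hi = min(p, n - length + 1)
    return hi - lo + 1 if hi >= lo else 0


def enumerate_peptide_pairs(
    wt_protein: str,
    mutation: SomaticMutation,
    lengths: Sequence[int] = DEFAULT_LENGTHS,
    report: EnumerationReport | None = None,
) -> list[PeptidePair]:
    """All MT/WT peptide pairs of the given lengths spanning the mutation.

    Windows containing a non-canonical residue (U, X, ...) are dropped and
    counted in ``report``.  Duplicate peptide strings from distinct starts
    are kept: downstream prediction dedups by string, calls keep windows.
    """
    if mutation.variant_classification != "missense":
        raise UnsupportedClassificationError(
            f"peptide pairs are defined for missense variants only, got "
            f"{mutation.variant_classification} ({mutation.gene_id} in {mutation.sample_id})"
        )
    p, ref_aa, alt_aa = mutation.protein_pos, mutation.ref_aa, mutation.alt_aa
    mt_protein = apply_missense(wt_protein, p, ref_aa, alt_aa)  # validates ref_aa
    n = len(wt_protein)
    pairs: list[PeptidePair] = []
    for length in lengths:
        for start in range(max(1, p - length + 1), min(p, n - length + 1) + 1):
            wt_pep = wt_protein[start - 1 : start - 1 + length]
            if not _CANONICAL_SET.issuperset(wt_pep):
                if report is not None:
                    report.n_windows_noncanonical += 1
                continue
            mt_pep = mt_protein[start - 1 : start - 1 + length]
            pairs.append(
                PeptidePair(
                    sample_id=mutation.sample_id,
                    gene_id=mutation.gene_id,
                    protein_pos=p,
                    ref_aa=ref_aa,
                    alt_aa=alt_aa,
                    length=length,
                    start=start,
                    mut_offset=p - start + 1,
                    mt_peptide=mt_pep,
                    wt_peptide=wt_pep,
                )
            )
    if report is not None:
        report.n_missense += 1
        report.n_pairs += len(pairs)
    return pairs


def enumerate_cohort_pairs(
    mutations: Iterable[SomaticMutation],
    proteome: Mapping[str, str],
    lengths: Sequence[int] = DEFAULT_LENGTHS,
) -> tuple[pd.DataFrame, EnumerationReport]:
    """Enumerate pairs for every missense mutation of a cohort.

    Non-missense records are skipped with per-class counts in the report;
    silent variants are ignored silently (they are not candidates at all).
    Returns a tidy DataFrame with one row per :class:`PeptidePair`.
    """
    report = EnumerationReport()
    rows: list[PeptidePair] = []
    for m in mutations:
        if m.variant_classification == "missense":
            rows.extend(enumerate_peptide_pairs(proteome[m.gene_id], m, lengths, report))
        elif m.is_nonsilent:
            report.note_skip(m.variant_classification)
    frame = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    return frame, report


def pairs_to_tsv(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def pairs_from_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
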