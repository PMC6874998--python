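"""Somatic variant handling: MAF I/O, population-frequency filtering and
mutation-landscape summaries.

The in-memory record is :class:`SomaticMutation`, a frozen dataclass holding
one nonsilent (or silent) variant observed in one tumor sample, with protein
coordinates when the variant changes a single residue.  Cohort-level
summaries (per-sample burden, classification/type/SNV-class tallies, the
gene x sample indicator matrix used for mutual-exclusivity screening) are
plain pandas objects.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError

#: Variant classifications that alter the protein product.  Splice-site and
#: indel classes carry no protein coordinates here but still count as
#: nonsilent for burden and gene-matrix purposes.
NONSILENT_CLASSES = frozenset(
    {"missense", "nonsense", "nonstop", "splice_site", "frameshift", "in_frame_indel"}
)

#: Classes whose records carry (protein_pos, ref_aa, alt_aa).
PROTEIN_COORD_CLASSES = frozenset({"missense", "nonsense", "nonstop"})

SNV_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# Canonical MAF Variant_Classification spellings -> internal tokens.
_MAF_CLASSIFICATION = {
    "missense_mutation": "missense",
    "nonsense_mutation": "nonsense",
    "nonstop_mutation": "nonstop",
    "splice_site": "splice_site",
    "silent": "silent",
    "frame_shift_del": "frameshift",
    "frame_shift_ins": "frameshift",
    "in_frame_del": "in_frame_indel",
    "in_frame_ins": "in_frame_indel",
}
_MAF_CLASSIFICATION_OUT = {
    "missense": "Missense_Mutation",
    "nonsense": "Nonsense_Mutation",
    "nonstop": "Nonstop_Mutation",
    "splice_site": "Splice_Site",
    "silent": "Silent",
    "frameshift": "Frame_Shift_Del",
    "in_frame_indel": "In_Frame_Del",
    "other": "Other",
}

MAF_COLUMNS = (
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "Variant_Type",
    "Tumor_Sample_Barcode",
    "Protein_position",
    "Amino_acids",
)


@dataclass(frozen=True, order=True)
class SomaticMutation:
    """One somatic variant in one sample.

    ``protein_pos``/``ref_aa``/``alt_aa`` are populated iff the
    classification is missense, nonsense or nonstop (1-based residue index,
    single-letter residues, ``*`` for a gained stop).
    """

    sample_id: str
    gene_id: str
    chrom: str
    genomic_pos: int
    ref_allele: str
    alt_allele: str
    variant_type: str  # SNP | INS | DEL
    variant_classification: str
    protein_pos: Optional[int] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None

    @property
    def is_nonsilent(self) -> bool:
        return self.variant_classification in NONSILENT_CLASSES

    @property
    def variant_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.genomic_pos, self.ref_allele, self.alt_allele)

    @property
    def aa_change(self) -> Optional[str]:
        if self.protein_pos is None:
            return None
        return f"{self.ref_aa}{self.protein_pos}{self.alt_aa}"


class PopulationAFTable:
    """Variant allele frequencies across four population databases.

    Emulates the common-variant resources used to pre-filter somatic calls
    (1000 Genomes, ESP6500, dbSNP, ExAC).  Missing entries mean "not seen in
    that database" and never cause a variant to be filtered.
    """

    AF_COLUMNS = ("af_1000g", "af_esp6500", "af_dbsnp", "af_exac")
    KEY_COLUMNS = ("chrom", "pos", "ref", "alt")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in (*self.KEY_COLUMNS, *self.AF_COLUMNS) if c not in frame.columns]
        if missing:
            raise FormatError(f"population AF table missing columns: {missing}")
        afs = frame[list(self.AF_COLUMNS)].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(afs, initial=0.0) < 0 or np.nanmax(afs, initial=0.0) > 1:
                raise ParameterError("allele frequencies must lie in [0, 1]")
        self.frame = frame.reset_index(drop=True)
        keys = zip(frame["chrom"], frame["pos"].astype(int), frame["ref"], frame["alt"])
        # max AF over the four databases, NaN-safe
        self._max_af = {
            key: (np.nan if np.all(np.isnan(row)) else np.nanmax(row))
            for key, row in zip(keys, afs)
        }

    def max_af(self, key: tuple[str, int, str, str]) -> float:
        """Largest AF over the four databases; NaN if the variant is absent."""
        return self._max_af.get(key, math.nan)

    def is_common(self, key: tuple[str, int, str, str], threshold: float = 0.005) -> bool:
        value = self.max_af(key)
        return bool(value > threshold) if not math.isnan(value) else False

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.9g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PopulationAFTable":
        return cls(pd.read_csv(path, sep="\t"))

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class LandscapeSummary:
    """Tabulations behind a cohort mutation-landscape figure."""

    classification_counts: pd.Series
    type_counts: pd.Series
    snv_class_counts: pd.Series
    per_sample_nonsilent: pd.Series
    gene_sample_counts: pd.Series  # gene -> #samples with >=1 nonsilent mutation

    def top_genes(self, k: int = 10) -> list[tuple[str, int]]:
        """Top-k genes by number of mutated samples, ties lexicographic."""
        items = sorted(self.gene_sample_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return [(g, int(n)) for g, n in items[:k]]

    def write_tsvs(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.classification_counts.rename_axis("classification").rename("n").to_csv(
            out / "landscape_classification.tsv", sep="\t"
        )
        self.type_counts.rename_axis("variant_type").rename("n").to_csv(
            out / "landscape_variant_type.tsv", sep="\t"
        )
        self.snv_class_counts.rename_axis("snv_class").rename("n").to_csv(
            out / "landscape_snv_class.tsv", sep="\t"
        )
        self.per_sample_nonsilent.rename_axis("sample_id").rename("n_nonsilent").to_csv(
            out / "landscape_per_sample.tsv", sep="\t"
        )
        pd.DataFrame(self.top_genes(k=len(self.gene_sample_counts)), columns=["gene_id", "n_samples"]).to_csv(
            out / "landscape_top_genes.tsv", sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# MAF I/O
# ---------------------------------------------------------------------------

def _resolve_columns(columns: Sequence[str]) -> dict[str, str]:
    lower = {c.lower(): c for c in columns}
    mapping = {}
    for want in MAF_COLUMNS:
        if want.lower() not in lower:
            raise FormatError(f"MAF is missing required column '{want}'")
        mapping[want] = lower[want.lower()]
    return mapping


def read_maf(path: str | Path) -> list[SomaticMutation]:
    """Read a minimal-dialect MAF into :class:`SomaticMutation` records.

    Unknown Variant_Classification values map to ``"other"``; blank protein
    fields become absent.  Raises :class:`FormatError` for missing columns or
    unparseable positions (reported with the 1-based data-row number).
    """
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    cols = _resolve_columns(frame.columns)
    records: list[SomaticMutation] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        row = dict(zip(frame.columns, row))
        try:
            genomic_pos = int(row[cols["Start_Position"]])
        except ValueError as exc:
            raise FormatError(f"unparseable Start_Position at data row {i}: "
                              f"{row[cols['Start_Position']]!r}") from exc
        raw_class = row[cols["Variant_Classification"]].strip().lower()
        classification = _MAF_CLASSIFICATION.get(raw_class, "other")
        prot = row[cols["Protein_position"]].strip()
        aa = row[cols["Amino_acids"]].strip()
        protein_pos = ref_aa = alt_aa = None
        if prot and classification in PROTEIN_COORD_CLASSES:
            try:
                protein_pos = int(prot)
            except ValueError as exc:
                raise FormatError(f"unparseable Protein_position at data row {i}: {prot!r}") from exc
            if "/" in aa:
                ref_aa, alt_aa = aa.split("/", 1)
        records.append(
            SomaticMutation(
                sample_id=row[cols["Tumor_Sample_Barcode"]],
                gene_id=row[cols["Hugo_Symbol"]],
                chrom=row[cols["Chromosome"]],
                genomic_pos=genomic_pos,
                ref_allele=row[cols["Reference_Allele"]],
                alt_allele=row[cols["Tumor_Seq_Allele2"]],
                variant_type=row[cols["Variant_Type"]].strip().upper() or "SNP",
                variant_classification=classification,
                protein_pos=protein_pos,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
            )
        )
    return records


def write_maf(mutations: Iterable[SomaticMutation], path: str | Path) -> None:
    rows = []
    for m in mutations:
        rows.append(
            {
                "Hugo_Symbol": m.gene_id,
                "Chromosome": m.chrom,
                "Start_Position": m.genomic_pos,
                "Reference_Allele": m.ref_allele,
                "Tumor_Seq_Allele2": m.alt_allele,
                "Variant_Classification": _MAF_CLASSIFICATION_OUT.get(
                    m.variant_classification, "Other"
                ),
                "Variant_Type": m.variant_type,
                "Tumor_Sample_Barcode": m.sample_id,
                "Protein_position": "" if m.protein_pos is None else m.protein_pos,
                "Amino_acids": "" if m.ref_aa is None else f"{m.ref_aa}/{m.alt_aa}",
            }
        )
    pd.DataFrame(rows, columns=list(MAF_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filtering and classification
# ---------------------------------------------------------------------------

def filter_common_variants(
    mutations: Sequence[SomaticMutation],
    af_table: PopulationAFTable,
    threshold: float = 0.005,
) -> list[SomaticMutation]:
    """Drop variants with AF strictly above ``threshold`` in any database.

    Variants absent from the table are kept.  Input order is preserved and a
    new list is returned; the operation is idempotent.
    """
    if not 0 <= threshold <= 1:
        raise ParameterError(f"threshold must be in [0, 1], got {threshold}")
    return [m for m in mutations if not af_table.is_common(m.variant_key, threshold)]


def snv_class(ref: str, alt: str) -> str:
    """Collapse a substitution to one of the six pyrimidine-reference classes.

    Purine-reference pairs are reverse-complemented, so e.g. G>A reports as
    C>T.  This is the standard convention for substitution-spectrum plots.
    """
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ParameterError(f"ref and alt must be single bases, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ParameterError("ref and alt must differ")
    if ref in "AG":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def summarize_landscape(mutations: Sequence[SomaticMutation]) -> LandscapeSummary:
    """Tabulate classification/type/SNV-class counts, per-sample burden and
    per-gene mutated-sample counts (nonsilent only for the last two)."""
    class_counts: Counter = Counter()
    type_counts: Counter = Counter()
    snv_counts: Counter = Counter({c: 0 for c in SNV_CLASSES})
    per_sample: Counter = Counter()
    gene_samples: dict[str, set[str]] = {}
    for m in mutations:
        class_counts[m.variant_classification] += 1
        type_counts[m.variant_type] += 1
        if m.variant_type == "SNP":
            snv_counts[snv_class(m.ref_allele, m.alt_allele)] += 1
        if m.is_nonsilent:
            per_sample[m.sample_id] += 1
            gene_samples.setdefault(m.gene_id, set()).add(m.sample_id)
    return LandscapeSummary(
        classification_counts=pd.Series(class_counts, dtype=int).sort_index(),
        type_counts=pd.Series(type_counts, dtype=int).sort_index(),
        snv_class_counts=pd.Series(snv_counts, dtype=int).loc[list(SNV_CLASSES)],
        per_sample_nonsilent=pd.Series(per_sample, dtype=int).sort_index(),
        gene_sample_counts=pd.Series(
            {g: len(s) for g, s in gene_samples.items()}, dtype=int
        ).sort_index(),
    )


def gene_sample_matrix(
    mutations: Sequence[SomaticMutation],
    genes: Optional[Sequence[str]] = None,
    samples: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Binary genes x samples matrix: 1 iff the sample has >=1 nonsilent
    mutation in the gene.  Row/column universes default to those observed."""
    if samples is None:
        samples = sorted({m.sample_id for m in mutations})
    if genes is None:
        genes = sorted({m.gene_id for m in mutations if m.is_nonsilent})
    matrix = pd.DataFrame(0, index=list(genes), columns=list(samples), dtype=np.int8)
    for m in mutations:
        if m.is_nonsilent and m.gene_id in matrix.index and m.sample_id in matrix.columns:
            matrix.at[m.gene_id, m.sample_id] = 1
    return matrix
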