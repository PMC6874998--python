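"""Synthetic gastric-tumor cohort generator.

Produces every input the downstream analysis needs — a proteome, per-sample
somatic mutations, clinical metadata, HLA class I genotypes, a population
allele-frequency table and a ground-truth binding model — with the
statistical structure the cohort analysis assumes:

* per-sample nonsilent burden from a negative binomial calibrated to a
  target median (tumor burden is overdispersed), multiplied by a
  configurable factor for patients aged >= 60;
* a C>T-dominant substitution spectrum (pyrimidine-reference classes);
* hotspot driver mutations inserted per sample at configured prevalences,
  producing recurrent neoantigen candidates;
* mutual-exclusivity structure between gene pairs, realized by thinning
  co-mutated samples down to a target odds ratio;
* HLA genotypes drawn per locus from a population allele-frequency list.

One master seed drives independent child streams per component, so the
whole fixture is byte-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .binding import PSSM, AlleleRegistry, ALLELE_PATTERN, PSSMPredictor
from .errors import ConsistencyError, ParameterError
from .peptides import CANONICAL_AA
from .variants import PopulationAFTable, SomaticMutation, SNV_CLASSES

_AA_ARRAY = np.array(list(CANONICAL_AA))

#: silent SNVs emitted per nonsilent mutation (Poisson mean multiplier),
#: emulating the silent fraction of exome-wide substitution calls.
SILENT_RATE = 0.4

#: composition of the nonsilent background (missense dominates; splice and
#: stop classes occur at exome-typical minor fractions).
BACKGROUND_CLASS_PROBS = {
    "missense": 0.909,
    "nonsense": 0.061,
    "nonstop": 0.002,
    "splice_site": 0.028,
}

# child-stream offsets from the master seed
_STREAMS = {"meta": 1, "burden": 2, "hotspot": 3, "background": 4,
            "hla": 5, "exclusivity": 6, "silent": 7, "variant": 8}


def _child_rng(seed: int, stream: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, _STREAMS[stream], extra])


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class Hotspot(NamedTuple):
    gene_id: str
    protein_pos: int
    ref_aa: str
    alt_aa: str
    prevalence: float


class ExclusivePair(NamedTuple):
    gene_a: str
    gene_b: str
    odds_ratio: float


@dataclass(frozen=True)
class ProteomeFixture:
    """Reference protein sequences, one transcript per gene."""

    records: tuple

    def __post_init__(self):
        ids = [g for g, _ in self.records]
        if len(set(ids)) != len(ids):
            raise ParameterError("gene_ids must be unique")
        for gene, seq in self.records:
            if len(seq) < 8:
                raise ParameterError(f"protein {gene} shorter than 8 residues")
            if not set(seq) <= set(CANONICAL_AA):
                raise ParameterError(f"protein {gene} has non-canonical residues")

    def as_dict(self) -> dict[str, str]:
        return dict(self.records)

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.records]

    def total_length(self) -> int:
        return sum(len(s) for _, s in self.records)


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    age: int
    sex: str            # male | female
    lauren: str         # intestinal | diffuse | mixed | NA
    stage: str          # I | II | III | IV | NA
    location: str       # antrum | body | cardia | other | NA


@dataclass(frozen=True)
class HLAGenotype:
    sample_id: str
    alleles: tuple

    def __post_init__(self):
        if not 1 <= len(self.alleles) <= 6:
            raise ParameterError("a genotype carries between 1 and 6 class I alleles")
        for allele in self.alleles:
            if not ALLELE_PATTERN.match(allele):
                raise ParameterError(f"malformed HLA allele name: {allele!r}")


@dataclass
class GroundTruthBinding:
    """The generative binding model: one PSSM per (allele, length) plus the
    per-tool score-noise SD used when simulating predictor panels."""

    pssms: dict
    noise_sd: float

    def registry(self) -> AlleleRegistry:
        reg = AlleleRegistry()
        for pssm in self.pssms.values():
            reg.add_pssm(pssm)
        return reg

    def make_tools(self, n_tools: int, seed: int = 0) -> list[PSSMPredictor]:
        """A panel of predictors observing this truth with independent noise."""
        reg = self.registry()
        return [
            PSSMPredictor(
                tool_id=f"tool{i + 1}",
                registry=reg,
                noise_sd=self.noise_sd,
                seed=(seed * 97 + i) & 0x7FFFFFFF,
            )
            for i in range(n_tools)
        ]

    def truth_score(self, peptide: str, allele: str) -> float:
        from .binding import score_peptide

        return score_peptide(self.pssms[(allele, len(peptide))], peptide)


@dataclass
class CohortConfig:
    """Parameters of the simulated cohort; defaults emulate a gastric-cancer
    exome cohort (median ~66 nonsilent mutations, C>T-dominant spectrum,
    higher burden in patients aged >= 60)."""

    n_samples: int
    burden_median: float = 66.0
    burden_dispersion: float = 2.0
    ct_fraction: float = 0.45
    hotspots: tuple = ()
    exclusive_pairs: tuple = ()
    age_effect: float = 1.5
    hla_frequencies: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        self.hotspots = tuple(Hotspot(*h) for h in self.hotspots)
        self.exclusive_pairs = tuple(ExclusivePair(*p) for p in self.exclusive_pairs)
        if not self.hla_frequencies:
            self.hla_frequencies = dict(DEFAULT_HLA_FREQUENCIES)
        self.validate()

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ParameterError("n_samples must be >= 1")
        if self.burden_median <= 0:
            raise ParameterError("burden_median must be positive")
        if self.burden_dispersion <= 0:
            raise ParameterError("burden_dispersion must be positive")
        if not 0 <= self.ct_fraction <= 1:
            raise ParameterError("ct_fraction must lie in [0, 1]")
        if self.age_effect <= 0:
            raise ParameterError("age_effect must be positive")
        for h in self.hotspots:
            if not 0 <= h.prevalence <= 1:
                raise ParameterError(f"hotspot prevalence outside [0, 1]: {h}")
        for p in self.exclusive_pairs:
            if not 0 < p.odds_ratio < 1:
                raise ParameterError(f"exclusive pair odds_ratio must be in (0, 1): {p}")
        for locus, freqs in self._by_locus().items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ParameterError(
                    f"HLA frequencies for locus {locus} sum to {total}, expected 1"
                )
            if any(not 0 <= f <= 1 for f in freqs.values()):
                raise ParameterError(f"HLA frequencies outside [0, 1] at locus {locus}")

    def _by_locus(self) -> dict[str, dict[str, float]]:
        loci: dict[str, dict[str, float]] = {}
        for allele, freq in self.hla_frequencies.items():
            if not ALLELE_PATTERN.match(allele):
                raise ParameterError(f"malformed HLA allele name: {allele!r}")
            loci.setdefault(allele[:5], {})[allele] = freq
        return loci


# Allele frequencies loosely shaped on common East-Asian class I alleles;
# each locus sums to exactly 1.
DEFAULT_HLA_FREQUENCIES = {
    "HLA-A11:01": 0.25, "HLA-A24:02": 0.20, "HLA-A02:01": 0.15,
    "HLA-A02:07": 0.10, "HLA-A33:03": 0.10, "HLA-A02:06": 0.05,
    "HLA-A30:01": 0.05, "HLA-A03:01": 0.04, "HLA-A68:01": 0.03,
    "HLA-A31:01": 0.03,
    "HLA-B40:01": 0.18, "HLA-B46:01": 0.14, "HLA-B58:01": 0.10,
    "HLA-B13:01": 0.08, "HLA-B15:01": 0.10, "HLA-B51:01": 0.08,
    "HLA-B07:02": 0.06, "HLA-B35:01": 0.10, "HLA-B57:01": 0.05,
    "HLA-B27:05": 0.05, "HLA-B08:01": 0.06,
    "HLA-C07:02": 0.25, "HLA-C01:02": 0.16, "HLA-C03:04": 0.14,
    "HLA-C03:03": 0.10, "HLA-C06:02": 0.08, "HLA-C08:01": 0.09,
    "HLA-C07:01": 0.06, "HLA-C12:03": 0.05, "HLA-C05:01": 0.04,
    "HLA-C04:01": 0.03,
}

#: a compact two-alleles-per-locus frequency set for fast simulations
SMALL_HLA_FREQUENCIES = {
    "HLA-A11:01": 0.6, "HLA-A24:02": 0.4,
    "HLA-B40:01": 0.6, "HLA-B46:01": 0.4,
    "HLA-C07:02": 0.6, "HLA-C01:02": 0.4,
}


# ---------------------------------------------------------------------------
# Proteome
# ---------------------------------------------------------------------------

def simulate_proteome(
    n_genes: int,
    min_len: int,
    max_len: int,
    seed: int,
    gene_ids: Optional[Sequence[str]] = None,
) -> ProteomeFixture:
    """Random proteome: lengths uniform on [min_len, max_len], residues
    i.i.d. uniform over the 20 canonical amino acids."""
    if n_genes < 1:
        raise ParameterError("n_genes must be >= 1")
    if not 8 <= min_len <= max_len:
        raise ParameterError("need 8 <= min_len <= max_len")
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    if gene_ids is None:
        gene_ids = [f"GENE{i + 1:04d}" for i in range(n_genes)]
    elif len(gene_ids) != n_genes:
        raise ParameterError("gene_ids length must equal n_genes")
    records = []
    for gene in gene_ids:
        length = int(rng.integers(min_len, max_len + 1))
        seq = "".join(_AA_ARRAY[rng.integers(0, 20, size=length)])
        records.append((gene, seq))
    return ProteomeFixture(records=tuple(records))


def force_residues(
    proteome: ProteomeFixture, assignments: Iterable[tuple[str, int, str]]
) -> ProteomeFixture:
    """Return a proteome with specific residues pinned (gene, 1-based pos,
    residue) — used to make hotspot reference residues consistent."""
    seqs = dict(proteome.records)
    for gene, pos, aa in assignments:
        if gene not in seqs:
            raise ParameterError(f"gene {gene} not in proteome")
        seq = seqs[gene]
        if not 1 <= pos <= len(seq):
            raise ParameterError(f"position {pos} outside {gene} (length {len(seq)})")
        seqs[gene] = seq[: pos - 1] + aa + seq[pos:]
    return ProteomeFixture(records=tuple(seqs.items()))


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _nb_mean_for_median(median: float, dispersion: float) -> float:
    """Mean of a negative binomial (size=dispersion) whose median equals the
    integer target.  The NB median is a step function of the mean; return
    the midpoint of the mean interval achieving the target."""
    target = int(round(median))

    def med(mu: float) -> int:
        return int(sps.nbinom.median(dispersion, dispersion / (dispersion + mu)))

    def lowest_mu_with_median_at_least(value: int) -> float:
        lo, hi = 1e-9, max(4.0 * value + 10.0, 10.0)
        while med(hi) < value:
            hi *= 2
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if med(mid) >= value:
                hi = mid
            else:
                lo = mid
        return hi

    lower = lowest_mu_with_median_at_least(target)
    upper = lowest_mu_with_median_at_least(target + 1)
    return 0.5 * (lower + upper)


# Table-1-shaped clinical strata of the 74-sample cohort.
_META_STRATA = {
    "age_ge60": 46 / 74,
    "sex": (("male", 52 / 74), ("female", 22 / 74)),
    "lauren": (("intestinal", 32 / 74), ("diffuse", 28 / 74), ("mixed", 10 / 74), ("NA", 4 / 74)),
    "stage": (("I", 7 / 74), ("II", 7 / 74), ("III", 51 / 74), ("IV", 9 / 74)),
    "location": (("antrum", 17 / 74), ("body", 31 / 74), ("cardia", 22 / 74), ("other", 4 / 74)),
}


def _draw_categorical(rng, spec):
    labels = [s[0] for s in spec]
    probs = np.array([s[1] for s in spec])
    return labels[int(rng.choice(len(labels), p=probs / probs.sum()))]


def _simulate_metadata(n_samples: int, seed: int) -> list[SampleMeta]:
    rng = _child_rng(seed, "meta")
    metas = []
    for i in range(n_samples):
        old = rng.random() < _META_STRATA["age_ge60"]
        age = int(rng.integers(60, 86)) if old else int(rng.integers(28, 60))
        metas.append(
            SampleMeta(
                sample_id=f"S{i + 1:04d}",
                age=age,
                sex=_draw_categorical(rng, _META_STRATA["sex"]),
                lauren=_draw_categorical(rng, _META_STRATA["lauren"]),
                stage=_draw_categorical(rng, _META_STRATA["stage"]),
                location=_draw_categorical(rng, _META_STRATA["location"]),
            )
        )
    return metas


def _simulate_genotypes(
    n_samples: int, sample_ids: Sequence[str], config: CohortConfig
) -> list[HLAGenotype]:
    rng = _child_rng(config.seed, "hla")
    loci = config._by_locus()
    genotypes = []
    for sid in sample_ids:
        alleles: set[str] = set()
        for locus in sorted(loci):
            names = sorted(loci[locus])
            probs = np.array([loci[locus][a] for a in names])
            draws = rng.choice(len(names), size=2, p=probs / probs.sum())
            alleles.update(names[d] for d in draws)
        genotypes.append(HLAGenotype(sample_id=sid, alleles=tuple(sorted(alleles))))
    return genotypes


_SNV_CLASS_BASES = {c: (c[0], c[2]) for c in SNV_CLASSES}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _variant_details(
    gene: str, protein_pos: int, alt_tag: str, ct_fraction: float, seed: int
) -> tuple[str, str, int]:
    """Deterministic nucleotide-level details (ref base, alt base, codon
    offset 0-2) for a variant, keyed on its protein-space identity so every
    sample carrying the same event shares one genomic variant."""
    key = zlib.crc32(f"{gene}:{protein_pos}:{alt_tag}".encode()) & 0x7FFFFFFF
    rng = np.random.default_rng([seed & 0x7FFFFFFF, _STREAMS["variant"], key])
    probs = np.full(6, (1.0 - ct_fraction) / 5.0)
    probs[SNV_CLASSES.index("C>T")] = ct_fraction
    cls = SNV_CLASSES[int(rng.choice(6, p=probs))]
    ref, alt = _SNV_CLASS_BASES[cls]
    if rng.random() < 0.5:  # report on the purine strand half the time
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return ref, alt, int(rng.integers(0, 3))


def _gene_coordinates(proteome: ProteomeFixture) -> dict[str, tuple[str, int]]:
    coords = {}
    for i, (gene, _) in enumerate(proteome.records):
        chrom = f"chr{(i % 22) + 1}"
        start = 10_000_000 * (i // 22) + 1_000_000
        coords[gene] = (chrom, start)
    return coords


def simulate_cohort(
    proteome: ProteomeFixture, config: CohortConfig
) -> tuple[list[SomaticMutation], list[SampleMeta], list[HLAGenotype]]:
    """Simulate mutations, metadata and HLA genotypes for one cohort.

    See the module docstring for the generative model.  Deterministic for a
    fixed config (the seed lives in the config).
    """
    seqs = proteome.as_dict()
    for h in config.hotspots:
        if h.gene_id not in seqs:
            raise ConsistencyError(f"hotspot gene {h.gene_id} not in proteome")
        seq = seqs[h.gene_id]
        if not 1 <= h.protein_pos <= len(seq):
            raise ConsistencyError(
                f"hotspot position {h.protein_pos} outside {h.gene_id}"
            )
        if seq[h.protein_pos - 1] != h.ref_aa:
            raise ConsistencyError(
                f"hotspot {h.gene_id} p.{h.ref_aa}{h.protein_pos}{h.alt_aa}: "
                f"proteome has {seq[h.protein_pos - 1]} at that position"
            )

    metas = _simulate_metadata(config.n_samples, config.seed)
    sample_ids = [m.sample_id for m in metas]
    genotypes = _simulate_genotypes(config.n_samples, sample_ids, config)

    # --- per-sample nonsilent burden ------------------------------------
    burden_rng = _child_rng(config.seed, "burden")
    mu = _nb_mean_for_median(config.burden_median, config.burden_dispersion)
    r = config.burden_dispersion
    base = burden_rng.negative_binomial(r, r / (r + mu), size=config.n_samples)
    ages = np.array([m.age for m in metas])
    burdens = np.where(
        ages >= 60, np.round(base * config.age_effect).astype(int), base
    )

    # --- hotspot carriage -----------------------------------------------
    hotspot_rng = _child_rng(config.seed, "hotspot")
    carried: dict[str, list[Hotspot]] = {sid: [] for sid in sample_ids}
    for h in config.hotspots:
        mask = hotspot_rng.random(config.n_samples) < h.prevalence
        for sid, hit in zip(sample_ids, mask):
            if hit:
                carried[sid].append(h)

    # --- background nonsilent mutations ---------------------------------
    bg_rng = _child_rng(config.seed, "background")
    lengths = np.array([len(s) for _, s in proteome.records])
    cum = np.cumsum(lengths)
    total = int(cum[-1])
    gene_ids = proteome.gene_ids
    class_names = list(BACKGROUND_CLASS_PROBS)
    class_probs = np.array(list(BACKGROUND_CLASS_PROBS.values()))
    class_probs = class_probs / class_probs.sum()

    background: dict[str, list[tuple[str, int, str]]] = {}
    for sid, burden in zip(sample_ids, burdens):
        n_bg = max(0, int(burden) - len(carried[sid]))
        sites = bg_rng.integers(0, total, size=n_bg)
        gidx = np.searchsorted(cum, sites, side="right")
        classes = bg_rng.choice(len(class_names), size=n_bg, p=class_probs)
        items = []
        for site, gi, ci in zip(sites, gidx, classes):
            gene = gene_ids[gi]
            pos = int(site - (cum[gi] - lengths[gi])) + 1
            cls = class_names[ci]
            if cls == "nonstop":
                pos = int(lengths[gi])  # stop-loss modeled at the final residue
            items.append((gene, pos, cls))
        background[sid] = items

    # --- mutual-exclusivity thinning ------------------------------------
    excl_rng = _child_rng(config.seed, "exclusivity")

    def gene_status(gene: str) -> np.ndarray:
        return np.array(
            [
                any(h.gene_id == gene for h in carried[sid])
                or any(g == gene for g, _, _ in background[sid])
                for sid in sample_ids
            ]
        )

    for pair in config.exclusive_pairs:
        status_a, status_b = gene_status(pair.gene_a), gene_status(pair.gene_b)
        a = int(np.sum(status_a & status_b))
        b = int(np.sum(status_a & ~status_b))
        c = int(np.sum(~status_a & status_b))
        d = int(np.sum(~status_a & ~status_b))
        if a == 0:
            continue
        current = (a * d) / (b * c) if b * c > 0 else np.inf
        if current <= pair.odds_ratio:
            continue
        t = pair.odds_ratio
        denom = a * (d + t * c)
        p_thin = (a * d - t * b * c) / denom if denom > 0 else 1.0
        p_thin = float(np.clip(p_thin, 0.0, 1.0))
        for sid, co in zip(sample_ids, status_a & status_b):
            if co and excl_rng.random() < p_thin:
                carried[sid] = [h for h in carried[sid] if h.gene_id != pair.gene_b]
                background[sid] = [
                    it for it in background[sid] if it[0] != pair.gene_b
                ]

    # --- silent passengers ----------------------------------------------
    silent_rng = _child_rng(config.seed, "silent")
    silent: dict[str, list[tuple[str, int]]] = {}
    for sid, burden in zip(sample_ids, burdens):
        n_silent = int(silent_rng.poisson(SILENT_RATE * int(burden)))
        sites = silent_rng.integers(0, total, size=n_silent)
        gidx = np.searchsorted(cum, sites, side="right")
        silent[sid] = [
            (gene_ids[gi], int(site - (cum[gi] - lengths[gi])) + 1)
            for site, gi in zip(sites, gidx)
        ]

    # --- materialize records --------------------------------------------
    coords = _gene_coordinates(proteome)
    mutations: list[SomaticMutation] = []
    for sid in sample_ids:
        seen: set[tuple[str, int]] = set()

        def emit(gene, pos, classification, ref_aa, alt_aa, alt_tag):
            if (gene, pos) in seen:
                return
            seen.add((gene, pos))
            ref_b, alt_b, offset = _variant_details(
                gene, pos, alt_tag, config.ct_fraction, config.seed
            )
            chrom, start = coords[gene]
            mutations.append(
                SomaticMutation(
                    sample_id=sid,
                    gene_id=gene,
                    chrom=chrom,
                    genomic_pos=start + 3 * (pos - 1) + offset,
                    ref_allele=ref_b,
                    alt_allele=alt_b,
                    variant_type="SNP",
                    variant_classification=classification,
                    protein_pos=pos if classification in ("missense", "nonsense", "nonstop") else None,
                    ref_aa=ref_aa if classification in ("missense", "nonsense", "nonstop") else None,
                    alt_aa=alt_aa if classification in ("missense", "nonsense", "nonstop") else None,
                )
            )

        for h in carried[sid]:
            emit(h.gene_id, h.protein_pos, "missense", h.ref_aa, h.alt_aa, h.alt_aa)
        for gene, pos, cls in background[sid]:
            ref_aa = seqs[gene][pos - 1]
            if cls == "missense":
                alt_aa = str(
                    bg_rng.choice([aa for aa in CANONICAL_AA if aa != ref_aa])
                )
            elif cls == "nonsense":
                alt_aa = "*"
            elif cls == "nonstop":
                alt_aa = str(
                    bg_rng.choice([aa for aa in CANONICAL_AA if aa != ref_aa])
                )
            else:  # splice_site: no protein-space change
                alt_aa = "splice"
            emit(gene, pos, cls, ref_aa, alt_aa, alt_aa)
        for gene, pos in silent[sid]:
            emit(gene, pos, "silent", None, None, "silent")

    return mutations, metas, genotypes


# ---------------------------------------------------------------------------
# Population allele frequencies
# ---------------------------------------------------------------------------

def simulate_population_af(
    mutations: Sequence[SomaticMutation], common_fraction: float, seed: int
) -> PopulationAFTable:
    """Assign population AFs to the cohort's distinct variants.

    A random ``common_fraction`` of distinct variants receives AF > 0.5% in
    at least one of the four database columns (so the common-variant filter
    removes exactly those); the rest are absent or rare (AF <= 0.5%)."""
    if not 0 <= common_fraction <= 1:
        raise ParameterError("common_fraction must lie in [0, 1]")
    keys = sorted({m.variant_key for m in mutations})
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 17])
    n_common = int(round(common_fraction * len(keys)))
    common_idx = set(rng.choice(len(keys), size=n_common, replace=False)) if n_common else set()
    rows = []
    for i, (chrom, pos, ref, alt) in enumerate(keys):
        afs = np.full(4, np.nan)
        if i in common_idx:
            n_db = int(rng.integers(1, 5))
            cols = rng.choice(4, size=n_db, replace=False)
            afs[cols] = np.exp(rng.uniform(np.log(0.006), np.log(0.5), size=n_db))
        else:
            if rng.random() < 0.5:  # seen but rare
                col = int(rng.integers(0, 4))
                afs[col] = rng.uniform(0.0, 0.005)
        rows.append({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                     **dict(zip(PopulationAFTable.AF_COLUMNS, afs))})
    frame = pd.DataFrame(
        rows, columns=list(PopulationAFTable.KEY_COLUMNS) + list(PopulationAFTable.AF_COLUMNS)
    )
    return PopulationAFTable(frame)


# ---------------------------------------------------------------------------
# Ground-truth binding model
# ---------------------------------------------------------------------------

#: baseline PSSM cell value; peptides near this score sit around 224 nM,
#: so only motif-matching peptides cross the 500 nM binder threshold the
#: way real predictors are selective.
BASELINE_WEIGHT = 0.30
_ANCHOR_SCALE = 1.0
_NONANCHOR_SCALE = 0.3

DEFAULT_LENGTHS = (8, 9, 10, 11)


def simulate_binding_truth(
    alleles: Sequence[str],
    motif_strength: float = 0.9,
    noise_sd: float = 0.05,
    seed: int = 0,
    lengths: Sequence[int] = DEFAULT_LENGTHS,
) -> GroundTruthBinding:
    """Generate one generative PSSM per (allele, length).

    Cells are ``BASELINE_WEIGHT`` plus uniform dispersion scaled by
    ``motif_strength``, with anchor positions (2 and the C-terminus) given
    elevated dispersion — zero strength collapses every matrix to a
    constant.  Simulated tools later observe these matrices plus Gaussian
    score noise of SD ``noise_sd``."""
    if not alleles:
        raise ParameterError("alleles must be non-empty")
    if motif_strength < 0 or noise_sd < 0:
        raise ParameterError("motif_strength and noise_sd must be >= 0")
    pssms = {}
    for allele in alleles:
        for length in lengths:
            rng = np.random.default_rng(
                [seed & 0x7FFFFFFF, zlib.crc32(allele.encode()) & 0x7FFFFFFF, length]
            )
            u = rng.uniform(-0.5, 0.5, size=(20, length))
            scale = np.full(length, _NONANCHOR_SCALE)
            scale[1] = _ANCHOR_SCALE
            scale[length - 1] = _ANCHOR_SCALE
            weights = np.clip(BASELINE_WEIGHT + motif_strength * scale * u, 0.0, 1.0)
            pssms[(allele, length)] = PSSM(allele=allele, length=length, weights=weights)
    return GroundTruthBinding(pssms=pssms, noise_sd=noise_sd)


def designed_binder_truth(
    alleles: Sequence[str],
    penalized_aa: str,
    high: float = 0.8,
    low: float = 0.45,
    noise_sd: float = 0.0,
    lengths: Sequence[int] = DEFAULT_LENGTHS,
) -> GroundTruthBinding:
    """A designed (non-random) truth guaranteeing calls for mutations away
    from ``penalized_aa``.

    Every cell is ``high`` except the ``penalized_aa`` row, which is
    ``low``.  Then (a) every peptide scores >= ``low`` = 381 nM < 500 nM at
    the defaults, so the binder criterion always holds, and (b) a missense
    swap replacing ``penalized_aa`` raises the mutant score by
    ``(high-low)/L``, so the mutant-better-than-wild-type criterion holds
    strictly for every window.  Used for calibration experiments where the
    recurrence of an injected hotspot must be recovered exactly."""
    if penalized_aa not in CANONICAL_AA:
        raise ParameterError(f"penalized_aa must be canonical, got {penalized_aa!r}")
    row = CANONICAL_AA.index(penalized_aa)
    pssms = {}
    for allele in alleles:
        for length in lengths:
            weights = np.full((20, length), high)
            weights[row, :] = low
            pssms[(allele, length)] = PSSM(allele=allele, length=length, weights=weights)
    return GroundTruthBinding(pssms=pssms, noise_sd=noise_sd)


# ---------------------------------------------------------------------------
# Study-shaped defaults
# ---------------------------------------------------------------------------

# Gene panel: recurrent-neoantigen genes, the TP53 exclusivity partners and
# frequently mutated passengers, with plausible (some truncated) protein
# lengths.
STUDY_GENE_LENGTHS = {
    "TP53": 393, "PIK3CA": 1068, "KRAS": 189, "PGM5": 562, "ERBB3": 1342,
    "C6": 934, "TRIM49C": 452, "OR4C16": 312, "CDH1": 882, "KMT2D": 1200,
    "RYR1": 1000, "ARID1A": 900, "TTN": 2000, "MUC16": 1500, "LRP1B": 1000,
    "SYNE1": 1200, "CSMD3": 900, "FAT4": 900,
}

# Recurrent hotspot mutations with per-sample prevalences shaped on the
# mutation frequencies of a 942-sample gastric-cancer meta-cohort.
STUDY_HOTSPOTS = [
    ("PGM5", 98, "I", "V", 0.028),
    ("TP53", 175, "R", "H", 0.027),
    ("TRIM49C", 327, "S", "R", 0.011),
    ("PIK3CA", 1047, "H", "R", 0.025),
    ("TP53", 273, "R", "H", 0.017),
    ("KRAS", 13, "G", "D", 0.016),
    ("ERBB3", 104, "V", "M", 0.012),
    ("C6", 817, "K", "T", 0.005),
    ("KRAS", 12, "G", "D", 0.017),
    ("TP53", 282, "R", "W", 0.015),
    ("OR4C16", 135, "S", "R", 0.006),
]

# Additional per-gene driver events (positions are arbitrary residues) that
# raise marginal gene prevalences to the levels the exclusivity structure
# needs: TP53 ~45%, partners >10%.
_DRIVER_BOOSTS = {
    "TP53": ([120, 132, 158, 196, 213, 220, 245, 248], 0.05),
    "CDH1": ([100, 200, 300], 0.04),
    "KMT2D": ([150, 300, 450], 0.04),
    "RYR1": ([150, 300, 450], 0.035),
    "PIK3CA": ([542, 545], 0.03),
    "ARID1A": ([250, 500, 750], 0.04),
}

STUDY_EXCLUSIVE_PAIRS = [
    ("TP53", "CDH1", 0.2),
    ("TP53", "KMT2D", 0.2),
    ("TP53", "RYR1", 0.2),
    ("TP53", "PIK3CA", 0.2),
    ("TP53", "ARID1A", 0.2),
]


def study_proteome(seed: int = 0, n_filler_genes: int = 42) -> ProteomeFixture:
    """The default simulated proteome: the named study genes at fixed
    lengths plus random filler genes, with hotspot reference residues
    pinned so the default hotspot list is consistent."""
    named = list(STUDY_GENE_LENGTHS)
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 99])
    records = []
    for gene in named:
        length = STUDY_GENE_LENGTHS[gene]
        records.append((gene, "".join(_AA_ARRAY[rng.integers(0, 20, size=length)])))
    filler = simulate_proteome(
        n_filler_genes, 300, 800, seed=(seed * 31 + 7) & 0x7FFFFFFF
    )
    proteome = ProteomeFixture(records=tuple(records) + filler.records)
    return force_residues(
        proteome, [(g, p, ref) for g, p, ref, _, _ in STUDY_HOTSPOTS]
    )


def study_config(
    proteome: ProteomeFixture,
    n_samples: int = 74,
    seed: int = 0,
    **overrides,
) -> CohortConfig:
    """Default cohort configuration emulating the study conditions."""
    seqs = proteome.as_dict()
    hotspots = list(STUDY_HOTSPOTS)
    for gene, (positions, prev) in _DRIVER_BOOSTS.items():
        for pos in positions:
            ref = seqs[gene][pos - 1]
            alt = CANONICAL_AA[(CANONICAL_AA.index(ref) + 1) % 20]
            hotspots.append((gene, pos, ref, alt, prev))
    params = dict(
        n_samples=n_samples,
        burden_median=66.0,
        burden_dispersion=2.0,
        ct_fraction=0.45,
        hotspots=tuple(hotspots),
        exclusive_pairs=tuple(STUDY_EXCLUSIVE_PAIRS),
        age_effect=1.5,
        hla_frequencies=dict(DEFAULT_HLA_FREQUENCIES),
        seed=seed,
    )
    params.update(overrides)
    return CohortConfig(**params)


# ---------------------------------------------------------------------------
# File writers / readers
# ---------------------------------------------------------------------------

def write_proteome_fasta(proteome: ProteomeFixture, path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=gene, description="") for gene, seq in proteome.records
    ]
    seqio_write(records, str(path), "fasta")


def read_proteome_fasta(path: str | Path) -> ProteomeFixture:
    from Bio.SeqIO import parse as seqio_parse

    records = tuple(
        (rec.id, str(rec.seq)) for rec in seqio_parse(str(path), "fasta")
    )
    return ProteomeFixture(records=records)


def write_metadata_tsv(metas: Sequence[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        [
            (m.sample_id, m.age, m.sex, m.lauren, m.stage, m.location)
            for m in metas
        ],
        columns=["sample_id", "age", "sex", "lauren", "stage", "location"],
    ).to_csv(path, sep="\t", index=False)


def read_metadata_tsv(path: str | Path) -> list[SampleMeta]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        SampleMeta(
            sample_id=row.sample_id,
            age=int(row.age),
            sex=row.sex,
            lauren=row.lauren,
            stage=row.stage,
            location=row.location,
        )
        for row in frame.itertuples(index=False)
    ]


def write_hla_tsv(genotypes: Sequence[HLAGenotype], path: str | Path) -> None:
    rows = []
    for g in genotypes:
        row = {"sample_id": g.sample_id}
        for i in range(6):
            row[f"allele_{i + 1}"] = g.alleles[i] if i < len(g.alleles) else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_hla_tsv(path: str | Path) -> list[HLAGenotype]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    genotypes = []
    for row in frame.itertuples(index=False):
        alleles = tuple(
            a for a in (getattr(row, f"allele_{i + 1}", "") for i in range(6)) if a
        )
        genotypes.append(HLAGenotype(sample_id=row.sample_id, alleles=alleles))
    return genotypes
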