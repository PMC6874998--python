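"""Peptide-MHC class I binding prediction.

All predictors are position-specific scoring matrices (PSSMs): a peptide's
score is the arithmetic mean of per-position residue weights, mapped to an
IC50 in nM through the standard ``IC50 = 50000^(1 - score)`` transform used
by the NetMHC family.  Alleles with no native matrix are covered by
pocket-similarity extrapolation: the matrices of known alleles are averaged
with weights proportional to pseudo-sequence identity (the PickPocket idea).

A "tool" is a :class:`PSSMPredictor`: a registry of matrices plus an
optional seeded Gaussian score perturbation, so a panel of tools behaves
like independent noisy predictors observing one underlying binding truth.
"""

from __future__ import annotations

import io
import re
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import CoverageError, ParameterError
from .peptides import CANONICAL_AA, PAIR_COLUMNS

IC50_MAX = 50000.0
_LN_IC50_MAX = np.log(IC50_MAX)

AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}

# byte -> residue index lookup (255 = invalid), for vectorized encoding
_AA_LUT = np.full(256, 255, dtype=np.uint8)
for _aa, _i in AA_INDEX.items():
    _AA_LUT[ord(_aa)] = _i

ALLELE_PATTERN = re.compile(r"^HLA-[ABC]\d{2}:\d{2}$")

PSEUDO_SEQUENCE_LENGTH = 34


def encode_peptides(peptides: Sequence[str], length: int) -> np.ndarray:
    """Encode equal-length peptides as an (n, length) residue-index array."""
    if len(peptides) == 0:
        return np.empty((0, length), dtype=np.uint8)
    raw = np.frombuffer("".join(peptides).encode("ascii"), dtype=np.uint8)
    codes = _AA_LUT[raw].reshape(len(peptides), length)
    if (codes == 255).any():
        bad = peptides[int(np.argwhere((codes == 255).any(axis=1))[0][0])]
        raise ParameterError(f"peptide contains non-canonical residue: {bad!r}")
    return codes


@dataclass(frozen=True)
class PSSM:
    """A 20 x L matrix of per-residue, per-position weights in [0, 1]."""

    allele: str
    length: int
    weights: np.ndarray  # shape (20, length)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (20, self.length):
            raise ParameterError(
                f"PSSM weights must be 20 x {self.length}, got {w.shape}"
            )
        if not np.all(np.isfinite(w)):
            raise ParameterError("PSSM weights must be finite")
        object.__setattr__(self, "weights", w)

    def score_many(self, codes: np.ndarray) -> np.ndarray:
        """Mean per-position weight for each encoded peptide row."""
        if codes.shape[1] != self.length:
            raise ParameterError(
                f"peptide length {codes.shape[1]} != PSSM length {self.length}"
            )
        return self.weights[codes, np.arange(self.length)].mean(axis=1)


def score_peptide(pssm: PSSM, peptide: str) -> float:
    """Score one peptide: arithmetic mean of its per-position weights."""
    if len(peptide) != pssm.length:
        raise ParameterError(
            f"peptide length {len(peptide)} != PSSM length {pssm.length}"
        )
    return float(pssm.score_many(encode_peptides([peptide], pssm.length))[0])


def score_to_ic50(score) -> np.ndarray | float:
    """Map a score in [0, 1] to IC50 nM: ``50000^(1 - score)``."""
    arr = np.asarray(score, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ParameterError("score must lie in [0, 1]")
    out = np.exp((1.0 - arr) * _LN_IC50_MAX)
    return float(out) if np.isscalar(score) or arr.ndim == 0 else out


def ic50_to_score(ic50) -> np.ndarray | float:
    """Inverse transform: ``1 - ln(ic50)/ln(50000)`` for ic50 in (0, 50000]."""
    arr = np.asarray(ic50, dtype=float)
    if np.any(arr <= 0) or np.any(arr > IC50_MAX):
        raise ParameterError("ic50 must lie in (0, 50000]")
    out = 1.0 - np.log(arr) / _LN_IC50_MAX
    return float(out) if np.isscalar(ic50) or arr.ndim == 0 else out


def default_pseudo_sequence(allele: str, length: int = PSEUDO_SEQUENCE_LENGTH) -> str:
    """Deterministic synthetic binding-pocket pseudo-sequence for an allele.

    A reproducible stand-in keyed on the allele name (not biologically
    sourced): alleles sharing a name share a pseudo-sequence across runs.
    """
    rng = np.random.default_rng(zlib.crc32(allele.encode()) & 0x7FFFFFFF)
    return "".join(rng.choice(list(CANONICAL_AA), size=length))


def pseudo_identity(a: str, b: str) -> float:
    """Fraction of identical positions between two pseudo-sequences."""
    if len(a) != len(b):
        raise ParameterError("pseudo-sequences must have equal length")
    return sum(x == y for x, y in zip(a, b)) / len(a)


class AlleleRegistry:
    """Maps alleles to pseudo-sequences and native PSSMs, and synthesizes
    matrices for uncovered alleles by pocket-similarity averaging."""

    def __init__(self, pseudo_sequences: Optional[Mapping[str, str]] = None):
        self.pseudo_sequences: dict[str, str] = dict(pseudo_sequences or {})
        self._native: dict[tuple[str, int], PSSM] = {}
        self._synth_cache: dict[tuple[str, int], PSSM] = {}

    def add_pssm(self, pssm: PSSM) -> None:
        self.pseudo_sequences.setdefault(pssm.allele, default_pseudo_sequence(pssm.allele))
        self._native[(pssm.allele, pssm.length)] = pssm
        self._synth_cache.clear()

    def pseudo_sequence(self, allele: str) -> str:
        if allele not in self.pseudo_sequences:
            self.pseudo_sequences[allele] = default_pseudo_sequence(allele)
        return self.pseudo_sequences[allele]

    def native_alleles(self, length: int) -> list[str]:
        return sorted(a for (a, L) in self._native if L == length)

    def has_native(self, allele: str, length: int) -> bool:
        return (allele, length) in self._native

    def resolve(self, allele: str, length: int) -> PSSM:
        """Native matrix if present, else similarity-weighted synthesis."""
        key = (allele, length)
        if key in self._native:
            return self._native[key]
        if key not in self._synth_cache:
            self._synth_cache[key] = synthesize_pssm(allele, self, length)
        return self._synth_cache[key]


def synthesize_pssm(target_allele: str, registry: AlleleRegistry, length: int) -> PSSM:
    """Extrapolate a matrix for an uncovered allele.

    The returned matrix is the average of all native matrices of the same
    length, weighted by normalized pseudo-sequence identity between the
    target and each source allele.  If every identity is zero the sources
    are weighted equally.  A native matrix for the target is returned as-is.
    """
    if registry.has_native(target_allele, length):
        return registry.resolve(target_allele, length)
    sources = registry.native_alleles(length)
    if not sources:
        raise CoverageError(
            f"no PSSM of length {length} available to synthesize {target_allele}; "
            f"registered alleles: {sorted({a for a, _ in registry._native})}"
        )
    target_pseudo = registry.pseudo_sequence(target_allele)
    identities = np.array(
        [pseudo_identity(target_pseudo, registry.pseudo_sequence(a)) for a in sources]
    )
    if identities.sum() == 0:
        weights = np.full(len(sources), 1.0 / len(sources))
    else:
        weights = identities / identities.sum()
    matrix = np.zeros((20, length))
    for w, allele in zip(weights, sources):
        matrix += w * registry.resolve(allele, length).weights
    return PSSM(allele=target_allele, length=length, weights=matrix)


_M64 = np.uint64(0xFFFFFFFFFFFFFFFF)


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """SplitMix64 finalizer: a high-quality vectorized integer mixer."""
    x = (x + np.uint64(0x9E3779B97F4A7C15)) & _M64
    x = ((x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & _M64
    x = ((x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & _M64
    return x ^ (x >> np.uint64(31))


def peptide_hashes(codes: np.ndarray) -> np.ndarray:
    """FNV-style content hash per encoded peptide row (uint64)."""
    h = np.full(codes.shape[0], 0xCBF29CE484222325, dtype=np.uint64)
    prime = np.uint64(1099511628211)
    for j in range(codes.shape[1]):
        h = ((h ^ (codes[:, j].astype(np.uint64) + np.uint64(1))) * prime) & _M64
    return h


def allele_hash(allele: str) -> np.uint64:
    return np.uint64(zlib.crc32(allele.encode()))


def score_noise(hashes: np.ndarray, seed: int, sd: float) -> np.ndarray:
    """Gaussian score perturbation as a pure function of candidate hash and
    tool seed: deterministic and invariant to candidate order and set."""
    from scipy.special import ndtri

    mixed = _splitmix64(hashes ^ _splitmix64(np.full(1, seed, dtype=np.uint64)))
    u = (mixed >> np.uint64(11)).astype(np.float64) * (2.0 ** -53)
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    return sd * ndtri(u)


@dataclass
class PSSMPredictor:
    """One binding-prediction "tool": a registry plus seeded score noise.

    With ``noise_sd > 0``, each candidate's score is perturbed by Gaussian
    noise that is a pure hash of (peptide content, allele, tool seed), then
    clipped to [0, 1] — deterministic, and invariant to both the order and
    the composition of the candidate set.
    """

    tool_id: str
    registry: AlleleRegistry
    noise_sd: float = 0.0
    seed: int = 0

    def score_block(self, peptides: Sequence[str], allele: str, length: int) -> np.ndarray:
        codes = encode_peptides(peptides, length)
        return self.score_codes(codes, allele, length)

    def score_codes(self, codes: np.ndarray, allele: str, length: int) -> np.ndarray:
        pssm = self.registry.resolve(allele, length)
        scores = pssm.score_many(codes)
        if self.noise_sd > 0:
            h = peptide_hashes(codes) ^ allele_hash(allele)
            scores = scores + score_noise(h, self.seed, self.noise_sd)
        return np.clip(scores, 0.0, 1.0)


PREDICTION_COLUMNS = ["peptide", "length", "allele", "tool_id", "score", "ic50"]


def _genotype_long(genotypes) -> pd.DataFrame:
    """Normalize HLAGenotype / list of HLAGenotype to (sample_id, allele),
    collapsing duplicate (homozygous) alleles."""
    if hasattr(genotypes, "alleles"):  # single genotype
        genotypes = [genotypes]
    rows = []
    for g in genotypes:
        for allele in sorted(set(g.alleles)):
            rows.append((g.sample_id, allele))
    return pd.DataFrame(rows, columns=["sample_id", "allele"])


def _as_pairs_frame(pairs) -> pd.DataFrame:
    if isinstance(pairs, pd.DataFrame):
        return pairs
    return pd.DataFrame(list(pairs), columns=PAIR_COLUMNS)


def predict_bindings(
    pairs,
    genotypes,
    tools: Sequence[PSSMPredictor],
    ic50_floor: float = 1.0,
) -> pd.DataFrame:
    """Score every (peptide, allele, tool) candidate for MT and WT peptides.

    ``pairs`` is a PeptidePair list or DataFrame; ``genotypes`` one
    :class:`~neocohort.simulate.HLAGenotype` or a list covering the cohort.
    Each distinct (peptide, allele) is scored once per tool; the consensus
    stage joins scores back to windows.  Returns a tidy DataFrame with
    columns ``peptide, length, allele, tool_id, score, ic50``.
    """
    if len(tools) < 2:
        raise ParameterError("at least two predictors are required for consensus calling")
    pairs = _as_pairs_frame(pairs)
    alleles = _genotype_long(genotypes)
    if pairs.empty or alleles.empty:
        return pd.DataFrame(columns=PREDICTION_COLUMNS)

    # candidate (peptide, allele) universe: both MT and WT strings per window
    merged = pairs[["sample_id", "mt_peptide", "wt_peptide", "length"]].merge(
        alleles, on="sample_id"
    )
    mt = merged[["mt_peptide", "length", "allele"]].rename(columns={"mt_peptide": "peptide"})
    wt = merged[["wt_peptide", "length", "allele"]].rename(columns={"wt_peptide": "peptide"})
    candidates = (
        pd.concat([mt, wt], ignore_index=True)
        .drop_duplicates()
        .sort_values(["allele", "length", "peptide"], kind="mergesort")
        .reset_index(drop=True)
    )

    frames = []
    for tool in sorted(tools, key=lambda t: t.tool_id):
        scores = np.empty(len(candidates))
        for (allele, length), block in candidates.groupby(["allele", "length"], sort=False):
            scores[block.index.to_numpy()] = tool.score_block(
                block["peptide"].tolist(), allele, int(length)
            )
        frame = candidates.copy()
        frame["tool_id"] = tool.tool_id
        frame["score"] = scores
        frame["ic50"] = np.maximum(score_to_ic50(scores), ic50_floor)
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    return out[PREDICTION_COLUMNS]


# ---------------------------------------------------------------------------
# PSSM file format: "#allele=<name> length=<L>" header, then a TSV with one
# row per residue and one column per position.
# ---------------------------------------------------------------------------

def write_pssm(pssm: PSSM, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#allele={pssm.allele} length={pssm.length}\n")
        fh.write("residue\t" + "\t".join(str(i + 1) for i in range(pssm.length)) + "\n")
        for i, aa in enumerate(CANONICAL_AA):
            fh.write(aa + "\t" + "\t".join(f"{w:.9g}" for w in pssm.weights[i]) + "\n")


def read_pssm(path: str | Path) -> PSSM:
    text = Path(path).read_text()
    header, _, body = text.partition("\n")
    m = re.match(r"#allele=(\S+) length=(\d+)$", header.strip())
    if not m:
        raise ParameterError(f"malformed PSSM header in {path}: {header!r}")
    allele, length = m.group(1), int(m.group(2))
    table = pd.read_csv(io.StringIO(body), sep="\t", index_col=0)
    weights = table.loc[list(CANONICAL_AA)].to_numpy(dtype=float)
    return PSSM(allele=allele, length=length, weights=weights)


def registry_from_dir(path: str | Path) -> AlleleRegistry:
    """Load every ``*.pssm.tsv`` file in a directory into a registry."""
    registry = AlleleRegistry()
    for file in sorted(Path(path).glob("*.pssm.tsv")):
        registry.add_pssm(read_pssm(file))
    return registry


def registry_to_dir(registry: AlleleRegistry, path: str | Path) -> None:
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    for (allele, length), pssm in sorted(registry._native.items()):
        safe = allele.replace("*", "").replace(":", "").replace("-", "_")
        write_pssm(pssm, out / f"{safe}_L{length}.pssm.tsv")
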