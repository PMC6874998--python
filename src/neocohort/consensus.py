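"""Consensus neoantigen calling.

A peptide window is called a neoantigen for a (sample, allele) when all
three criteria hold:

1. the peptide is 8-11 residues long (guaranteed upstream, re-checked);
2. the mutant IC50 is strictly below the threshold (default 500 nM) in at
   least ``min_tools`` predictors (default 2);
3. the consensus (median over tools, lower middle for even counts) mutant
   IC50 is strictly below the consensus wild-type IC50, i.e. the mutant
   binds more strongly than its wild-type counterpart.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .binding import _as_pairs_frame, _genotype_long
from .errors import IncompleteInputError, ParameterError

CALL_SORT_KEYS = ["sample_id", "gene_id", "protein_pos", "allele", "length", "start"]


def low_median(matrix: np.ndarray) -> np.ndarray:
    """Row-wise median taking the lower of the two middle values for even
    counts (deterministic, always an observed value)."""
    n = matrix.shape[1]
    return np.sort(matrix, axis=1)[:, (n - 1) // 2]


def call_neoantigens(
    predictions: pd.DataFrame,
    pairs,
    genotypes,
    ic50_threshold: float = 500.0,
    min_tools: int = 2,
) -> pd.DataFrame:
    """Apply the three consensus criteria to every (window, allele) candidate.

    ``predictions`` is the tidy frame from
    :func:`neocohort.binding.predict_bindings` and must cover the MT and WT
    peptide of every candidate for every tool.  Returns one row per call
    with per-tool IC50 columns (``mt_ic50_<tool>``/``wt_ic50_<tool>``),
    ``n_tools_passing`` and the consensus IC50s, sorted by
    (sample, gene, position, allele, length, start).
    """
    if ic50_threshold <= 0:
        raise ParameterError("ic50_threshold must be positive")
    if min_tools < 1:
        raise ParameterError("min_tools must be >= 1")
    pairs = _as_pairs_frame(pairs)
    alleles = _genotype_long(genotypes)
    tool_ids = sorted(predictions["tool_id"].unique()) if len(predictions) else []
    empty = _empty_calls(tool_ids)
    if pairs.empty or alleles.empty:
        return empty
    if min_tools > len(tool_ids):
        raise ParameterError(
            f"min_tools={min_tools} exceeds the {len(tool_ids)} configured tools"
        )

    candidates = pairs.merge(alleles, on="sample_id")
    if candidates.empty:
        return empty

    # wide IC50 lookup: (peptide, allele) x tool, joined twice (MT and WT)
    wide = (
        predictions.pivot_table(
            index=["peptide", "allele"], columns="tool_id", values="ic50", aggfunc="first"
        )[tool_ids]
        .reset_index()
    )
    tool_cols = list(tool_ids)
    mt_ic50 = (
        candidates[["mt_peptide", "allele"]]
        .merge(wide, how="left", left_on=["mt_peptide", "allele"], right_on=["peptide", "allele"])[tool_cols]
        .to_numpy()
    )
    wt_ic50 = (
        candidates[["wt_peptide", "allele"]]
        .merge(wide, how="left", left_on=["wt_peptide", "allele"], right_on=["peptide", "allele"])[tool_cols]
        .to_numpy()
    )
    for name, arr, pep_col in (("MT", mt_ic50, "mt_peptide"), ("WT", wt_ic50, "wt_peptide")):
        bad = np.isnan(arr).any(axis=1)
        if bad.any():
            row = candidates.iloc[int(np.flatnonzero(bad)[0])]
            raise IncompleteInputError(
                f"missing {name} prediction for peptide {row[pep_col]!r} / allele "
                f"{row['allele']} (sample {row['sample_id']}, gene {row['gene_id']})"
            )

    crit1 = candidates["length"].between(8, 11).to_numpy()
    crit2 = (mt_ic50 < ic50_threshold).sum(axis=1) >= min_tools
    consensus_mt = low_median(mt_ic50)
    consensus_wt = low_median(wt_ic50)
    crit3 = consensus_mt < consensus_wt
    keep = crit1 & crit2 & crit3

    calls = candidates.loc[keep].copy()
    for j, tool in enumerate(tool_ids):
        calls[f"mt_ic50_{tool}"] = mt_ic50[keep, j]
        calls[f"wt_ic50_{tool}"] = wt_ic50[keep, j]
    calls["n_tools_passing"] = (mt_ic50 < ic50_threshold).sum(axis=1)[keep]
    calls["consensus_mt_ic50"] = consensus_mt[keep]
    calls["consensus_wt_ic50"] = consensus_wt[keep]
    calls = calls.sort_values(CALL_SORT_KEYS, kind="mergesort").reset_index(drop=True)
    return calls


def predict_and_call(
    pairs,
    genotypes,
    tools,
    ic50_threshold: float = 500.0,
    min_tools: int = 2,
    ic50_floor: float = 1.0,
) -> pd.DataFrame:
    """Integer-coded scoring-and-calling path for cohort-scale runs.

    Produces exactly the calls of
    ``call_neoantigens(predict_bindings(pairs, genotypes, tools), ...)``
    (scores and noise are identical pure functions of peptide content,
    allele and tool seed) without materializing the tidy prediction frame,
    which matters at millions of candidates.
    """
    from .binding import (
        _as_pairs_frame,
        _genotype_long,
        allele_hash,
        encode_peptides,
        peptide_hashes,
        score_noise,
        score_to_ic50,
    )

    if len(tools) < 2:
        raise ParameterError("at least two predictors are required for consensus calling")
    if min_tools > len(tools):
        raise ParameterError(
            f"min_tools={min_tools} exceeds the {len(tools)} configured tools"
        )
    tools = sorted(tools, key=lambda t: t.tool_id)
    tool_ids = [t.tool_id for t in tools]
    pairs = _as_pairs_frame(pairs)
    allele_long = _genotype_long(genotypes)
    if pairs.empty or allele_long.empty:
        return _empty_calls(tool_ids)

    # --- candidate expansion: pair rows x the sample's alleles ----------
    allele_names, allele_inv = np.unique(allele_long["allele"], return_inverse=True)
    n_alleles = len(allele_names)
    sample_names, sample_inv = np.unique(allele_long["sample_id"], return_inverse=True)
    order = np.lexsort((allele_inv, sample_inv))
    flat_alleles = allele_inv[order]
    counts_per_sample = np.bincount(sample_inv, minlength=len(sample_names))
    sample_starts = np.concatenate([[0], np.cumsum(counts_per_sample)[:-1]])

    psid_codes, psid_uniques = pd.factorize(pairs["sample_id"].to_numpy())
    uniq_to_sample = np.searchsorted(sample_names, psid_uniques)
    uniq_known = (uniq_to_sample < len(sample_names)) & (
        sample_names[np.minimum(uniq_to_sample, len(sample_names) - 1)] == psid_uniques
    )
    known = uniq_known[psid_codes]
    if not known.all():
        pairs = pairs.loc[known].reset_index(drop=True)  # samples without genotypes
        if pairs.empty:
            return _empty_calls(tool_ids)
        psid_codes = psid_codes[known]
    pair_sample = uniq_to_sample[psid_codes]
    counts = counts_per_sample[pair_sample]
    total = int(counts.sum())
    pair_idx = np.repeat(np.arange(len(pairs)), counts)
    cum = np.concatenate([[0], np.cumsum(counts)[:-1]])
    within = np.arange(total) - np.repeat(cum, counts)
    cand_allele = flat_alleles[np.repeat(sample_starts[pair_sample], counts) + within]

    # --- peptide universe and (peptide, allele) keys --------------------
    mt_strings = pairs["mt_peptide"].to_numpy()
    wt_strings = pairs["wt_peptide"].to_numpy()
    pep_codes, pep_uniques = pd.factorize(np.concatenate([mt_strings, wt_strings]))
    mt_code, wt_code = pep_codes[: len(pairs)], pep_codes[len(pairs):]
    mt_keys = mt_code[pair_idx].astype(np.int64) * n_alleles + cand_allele
    wt_keys = wt_code[pair_idx].astype(np.int64) * n_alleles + cand_allele
    all_keys = np.sort(np.concatenate([mt_keys, wt_keys]), kind="stable")
    new_value = np.empty(all_keys.size, dtype=bool)
    new_value[0] = True
    np.not_equal(all_keys[1:], all_keys[:-1], out=new_value[1:])
    uniq_keys = all_keys[new_value]
    mt_pos = np.searchsorted(uniq_keys, mt_keys)
    wt_pos = np.searchsorted(uniq_keys, wt_keys)
    uniq_pep = (uniq_keys // n_alleles).astype(np.intp)
    uniq_allele = (uniq_keys % n_alleles).astype(np.intp)

    # --- encode peptides once per length --------------------------------
    pair_lengths = pairs["length"].to_numpy(dtype=np.int64)
    pep_lengths = np.empty(len(pep_uniques), dtype=np.int64)
    pep_lengths[mt_code] = pair_lengths
    pep_lengths[wt_code] = pair_lengths
    enc: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for length in np.unique(pep_lengths):
        idx = np.flatnonzero(pep_lengths == length)
        enc[int(length)] = (idx, encode_peptides(pep_uniques[idx], int(length)))
    row_of_pep = np.empty(len(pep_uniques), dtype=np.intp)
    for length, (idx, _) in enc.items():
        row_of_pep[idx] = np.arange(len(idx))
    pep_hash = np.empty(len(pep_uniques), dtype=np.uint64)
    for length, (idx, codes) in enc.items():
        pep_hash[idx] = peptide_hashes(codes)
    allele_hashes = np.array([allele_hash(a) for a in allele_names], dtype=np.uint64)
    cand_hash = pep_hash[uniq_pep] ^ allele_hashes[uniq_allele]

    # --- per-tool scores over the unique candidate set ------------------
    n_tools = len(tools)
    ic50 = np.empty((len(uniq_keys), n_tools))
    for a in range(n_alleles):
        a_mask = uniq_allele == a
        for length, (idx, codes) in enc.items():
            sel = np.flatnonzero(a_mask & (pep_lengths[uniq_pep] == length))
            if not sel.size:
                continue
            rows = row_of_pep[uniq_pep[sel]]
            for j, tool in enumerate(tools):
                pssm = tool.registry.resolve(str(allele_names[a]), length)
                scores = pssm.score_many(codes[rows])
                if tool.noise_sd > 0:
                    scores = scores + score_noise(cand_hash[sel], tool.seed, tool.noise_sd)
                ic50[sel, j] = np.maximum(
                    score_to_ic50(np.clip(scores, 0.0, 1.0)), ic50_floor
                )

    # --- criteria --------------------------------------------------------
    mt_ic50 = ic50[mt_pos]
    wt_ic50 = ic50[wt_pos]
    lengths_arr = pairs["length"].to_numpy()[pair_idx]
    crit1 = (lengths_arr >= 8) & (lengths_arr <= 11)
    n_passing = (mt_ic50 < ic50_threshold).sum(axis=1)
    consensus_mt = low_median(mt_ic50)
    consensus_wt = low_median(wt_ic50)
    keep = crit1 & (n_passing >= min_tools) & (consensus_mt < consensus_wt)

    calls = pairs.iloc[pair_idx[keep]].reset_index(drop=True)
    calls["allele"] = allele_names[cand_allele[keep]]
    for j, tool_id in enumerate(tool_ids):
        calls[f"mt_ic50_{tool_id}"] = mt_ic50[keep, j]
        calls[f"wt_ic50_{tool_id}"] = wt_ic50[keep, j]
    calls["n_tools_passing"] = n_passing[keep]
    calls["consensus_mt_ic50"] = consensus_mt[keep]
    calls["consensus_wt_ic50"] = consensus_wt[keep]
    calls = calls.sort_values(CALL_SORT_KEYS, kind="mergesort").reset_index(drop=True)
    return calls


def _empty_calls(tool_ids: Sequence[str]) -> pd.DataFrame:
    from .peptides import PAIR_COLUMNS

    columns = (
        PAIR_COLUMNS
        + ["allele"]
        + [f"mt_ic50_{t}" for t in tool_ids]
        + [f"wt_ic50_{t}" for t in tool_ids]
        + ["n_tools_passing", "consensus_mt_ic50", "consensus_wt_ic50"]
    )
    return pd.DataFrame(columns=columns)


def calls_to_tsv(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index=False, float_format="%.9g")


def calls_from_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
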