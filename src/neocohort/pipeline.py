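"""Run orchestration: simulate -> call -> stats with manifests.

Each stage reads/writes plain TSV/FASTA artifacts, logs per-stage record
counts to stderr and drops a JSON manifest (config digest, input digests,
parameters, per-stage counts) so a run can be reproduced byte-for-byte.
Floats are serialized with 9 significant digits throughout.
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .binding import PSSMPredictor, predict_bindings, registry_from_dir, registry_to_dir
from .consensus import call_neoantigens, calls_from_tsv, calls_to_tsv
from .errors import (
    ParameterError,
    ReconciliationError,
    StratificationError,
    UndefinedCorrelationError,
)
from .peptides import DEFAULT_LENGTHS, enumerate_cohort_pairs
from .simulate import (
    CohortConfig,
    GroundTruthBinding,
    read_hla_tsv,
    read_metadata_tsv,
    read_proteome_fasta,
    simulate_binding_truth,
    simulate_cohort,
    simulate_population_af,
    simulate_proteome,
    write_hla_tsv,
    write_metadata_tsv,
    write_proteome_fasta,
)
from .stats import (
    STRATIFIERS,
    compare_subgroups,
    exclusivity_to_frame,
    mutual_exclusivity_screen,
    neoantigen_load,
    panel_coverage,
    recurrent_neoantigens,
    select_panel_greedy,
    spearman_rho,
    subgroups_to_frame,
)
from .variants import (
    PopulationAFTable,
    filter_common_variants,
    gene_sample_matrix,
    read_maf,
    write_maf,
)

FLOAT_FORMAT = "%.9g"


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _log(stage: str, message: str) -> None:
    print(f"[neocohort:{stage}] {message}", file=sys.stderr)


def _write_manifest(out_dir: Path, stage: str, payload: dict) -> None:
    payload = {"package_version": __version__, "stage": stage, **payload}
    (out_dir / "manifest.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

REQUIRED_SIMULATE_KEYS = ("seed", "cohort")


def load_simulation_config(path: str | Path) -> dict:
    """Parse and validate a simulation YAML config.

    Layout: top-level ``seed``; ``proteome`` (n_genes, min_len, max_len);
    ``cohort`` mirroring :class:`~neocohort.simulate.CohortConfig`;
    ``binding`` (motif_strength, noise_sd, n_tools).
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ParameterError("simulation config must be a mapping")
    for key in REQUIRED_SIMULATE_KEYS:
        if key not in raw:
            raise ParameterError(f"simulation config missing required key '{key}'")
    return raw


def simulate_run(
    config: Mapping,
    out_dir: str | Path,
    proteome=None,
    truth: Optional[GroundTruthBinding] = None,
) -> dict:
    """Generate and write the full synthetic fixture.

    ``config`` is the parsed YAML mapping (or equivalent dict).  A
    pre-built proteome/binding truth may be passed to override the config
    sections.  Writes proteome FASTA, MAF, metadata TSV, HLA TSV, AF TSV,
    ground-truth PSSMs and a manifest; returns the stage counts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])

    if proteome is None:
        pconf = dict(config.get("proteome", {}))
        proteome = simulate_proteome(
            n_genes=int(pconf.get("n_genes", 60)),
            min_len=int(pconf.get("min_len", 300)),
            max_len=int(pconf.get("max_len", 800)),
            seed=seed,
        )
    cohort_kwargs = dict(config["cohort"])
    cohort_kwargs.setdefault("seed", seed)
    cohort_kwargs["hotspots"] = tuple(
        tuple(h) if not isinstance(h, dict) else
        (h["gene_id"], int(h["protein_pos"]), h["ref_aa"], h["alt_aa"], float(h["prevalence"]))
        for h in cohort_kwargs.get("hotspots", ())
    )
    cohort_kwargs["exclusive_pairs"] = tuple(
        tuple(p) if not isinstance(p, dict) else
        (p["gene_a"], p["gene_b"], float(p["odds_ratio"]))
        for p in cohort_kwargs.get("exclusive_pairs", ())
    )
    cohort = CohortConfig(**cohort_kwargs)

    mutations, metas, genotypes = simulate_cohort(proteome, cohort)
    bconf = dict(config.get("binding", {}))
    if truth is None:
        truth = simulate_binding_truth(
            alleles=sorted(cohort.hla_frequencies),
            motif_strength=float(bconf.get("motif_strength", 0.9)),
            noise_sd=float(bconf.get("noise_sd", 0.05)),
            seed=seed,
        )
    af_table = simulate_population_af(
        mutations, common_fraction=float(config.get("common_fraction", 0.05)), seed=seed
    )

    write_proteome_fasta(proteome, out / "proteome.fasta")
    write_maf(mutations, out / "mutations.maf")
    write_metadata_tsv(metas, out / "metadata.tsv")
    write_hla_tsv(genotypes, out / "hla.tsv")
    af_table.to_tsv(out / "population_af.tsv")
    registry_to_dir(truth.registry(), out / "truth")
    (out / "tools.yaml").write_text(
        yaml.safe_dump(
            {
                "n_tools": int(bconf.get("n_tools", 3)),
                "noise_sd": truth.noise_sd,
                "seed": seed,
            }
        )
    )

    counts = {
        "n_genes": len(proteome.records),
        "n_samples": len(metas),
        "n_mutations": len(mutations),
        "n_alleles": len(cohort.hla_frequencies),
        "n_af_rows": len(af_table),
    }
    _log("simulate", f"wrote {counts['n_mutations']} mutations for "
                     f"{counts['n_samples']} samples to {out}")
    _write_manifest(out, "simulate", {
        "seed": seed,
        "config_digest": hashlib.sha256(
            json.dumps(_jsonable(config), sort_keys=True).encode()
        ).hexdigest()[:16],
        "counts": counts,
    })
    return counts


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


# ---------------------------------------------------------------------------
# call
# ---------------------------------------------------------------------------

def call_run(
    maf: str | Path,
    hla: str | Path,
    proteome: str | Path,
    af_table: str | Path,
    truth_dir: str | Path,
    out_dir: str | Path,
    ic50_threshold: float = 500.0,
    min_tools: int = 2,
    lengths: Sequence[int] = DEFAULT_LENGTHS,
    n_tools: int = 3,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> dict:
    """Filter variants, enumerate peptide pairs, predict bindings and call
    neoantigens; writes ``calls.tsv`` plus a manifest of stage counts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if min_tools > n_tools:
        raise ParameterError(f"min_tools={min_tools} exceeds n_tools={n_tools}")

    inputs = {name: Path(p) for name, p in
              (("maf", maf), ("hla", hla), ("proteome", proteome), ("af_table", af_table))}
    mutations = read_maf(inputs["maf"])
    genotypes = read_hla_tsv(inputs["hla"])
    prot = read_proteome_fasta(inputs["proteome"])
    afs = PopulationAFTable.from_tsv(inputs["af_table"])
    registry = registry_from_dir(truth_dir)
    tools = [
        PSSMPredictor(tool_id=f"tool{i + 1}", registry=registry,
                      noise_sd=noise_sd, seed=(seed * 97 + i) & 0x7FFFFFFF)
        for i in range(n_tools)
    ]

    kept = filter_common_variants(mutations, afs)
    _log("call", f"common-variant filter: {len(mutations)} -> {len(kept)}")
    pairs, report = enumerate_cohort_pairs(kept, prot.as_dict(), lengths)
    _log("call", f"peptide pairs: {len(pairs)} from {report.n_missense} missense "
                 f"(skipped {report.skipped_by_class})")
    predictions = predict_bindings(pairs, genotypes, tools)
    _log("call", f"predictions: {len(predictions)}")
    calls = call_neoantigens(predictions, pairs, genotypes,
                             ic50_threshold=ic50_threshold, min_tools=min_tools)
    _log("call", f"neoantigen calls: {len(calls)}")
    calls_to_tsv(calls, out / "calls.tsv")

    counts = {
        "variants_in": len(mutations),
        "variants_kept": len(kept),
        "pairs": len(pairs),
        "pairs_skipped_by_class": report.skipped_by_class,
        "predictions": len(predictions),
        "calls": len(calls),
    }
    _write_manifest(out, "call", {
        "seed": seed,
        "inputs": {k: _digest(v) for k, v in inputs.items()},
        "params": {"ic50_threshold": ic50_threshold, "min_tools": min_tools,
                   "lengths": list(lengths), "n_tools": n_tools, "noise_sd": noise_sd},
        "counts": counts,
    })
    return counts


# ---------------------------------------------------------------------------
# stats
# ---------------------------------------------------------------------------

def stats_run(
    calls: str | Path,
    maf: str | Path,
    metadata: str | Path,
    out_dir: str | Path,
    min_samples: int = 2,
    panel_size: int = 10,
    identity: str = "peptide",
    correction: str = "none",
    exclusivity_top_genes: int = 25,
) -> dict:
    """Cohort statistics: load, recurrence, panel, exclusivity, subgroup
    comparisons and the load-burden correlation; writes five TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    calls_frame = calls_from_tsv(calls) if not isinstance(calls, pd.DataFrame) else calls
    mutations = read_maf(maf)
    metas = read_metadata_tsv(metadata)

    loads = neoantigen_load(calls_frame, mutations, metas)
    loads.to_csv(out / "load.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)

    recurrence = recurrent_neoantigens(calls_frame, min_samples=min_samples, identity=identity)
    rec_out = recurrence.copy()
    if len(rec_out):
        rec_out["carriers"] = rec_out["carriers"].map(";".join)
        rec_out["freq"] = rec_out["n_samples"] / len(loads)
    rec_out.to_csv(out / "recurrence.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)

    panel = select_panel_greedy(recurrence, k=panel_size) if len(recurrence) else []
    cumulative = []
    for i in range(len(panel)):
        cumulative.append(
            panel_coverage(calls_frame, panel[: i + 1], loads["sample_id"], identity=identity)
        )
    pd.DataFrame({"identity": panel, "cumulative_coverage": cumulative}).to_csv(
        out / "panel.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
    )
    coverage = cumulative[-1] if cumulative else 0.0

    matrix = gene_sample_matrix(mutations, samples=list(loads["sample_id"]))
    top = matrix.sum(axis=1).sort_values(ascending=False, kind="mergesort")
    top_genes = sorted(top.index[: min(exclusivity_top_genes, len(top))])
    excl = mutual_exclusivity_screen(
        matrix.loc[top_genes], correction=correction if correction != "none" else "none"
    )
    exclusivity_to_frame(excl).to_csv(
        out / "exclusivity.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
    )

    subgroup_rows = []
    skipped = []
    for strat in STRATIFIERS:
        try:
            subgroup_rows.extend(compare_subgroups(loads, strat))
        except StratificationError as exc:
            skipped.append(str(exc))
    subgroups_to_frame(subgroup_rows).to_csv(
        out / "subgroups.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
    )

    try:
        correlation = spearman_rho(loads["n_nonsilent"], loads["n_neoantigens"])
        rho, rho_p = correlation.statistic, correlation.p_value
    except (ParameterError, UndefinedCorrelationError):
        rho, rho_p = float("nan"), float("nan")  # degenerate loads (e.g. all zero)
    summary = {
        "n_samples": len(loads),
        "median_nonsilent": float(loads["n_nonsilent"].median()),
        "median_neoantigens": float(loads["n_neoantigens"].median()),
        "spearman_rho": rho,
        "spearman_p": rho_p,
        "n_recurrent": int(len(recurrence)),
        "panel_size": len(panel),
        "panel_coverage": coverage,
        "n_exclusive_p05": sum(
            1 for r in excl if r.direction == "exclusive" and r.test.p_value < 0.05
        ),
        "stratifiers_skipped": skipped,
    }
    _log("stats", f"median burden {summary['median_nonsilent']:.0f}, "
                  f"median load {summary['median_neoantigens']:.0f}, "
                  f"rho {summary['spearman_rho']:.3f}, "
                  f"panel coverage {100 * coverage:.1f}%")
    _write_manifest(out, "stats", {
        "inputs": {
            name: _digest(Path(p)) if not isinstance(p, pd.DataFrame) else "in-memory"
            for name, p in (("calls", calls), ("maf", maf), ("metadata", metadata))
        },
        "params": {"min_samples": min_samples, "panel_size": panel_size,
                   "identity": identity, "correction": correction},
        "summary": _jsonable(summary),
    })
    return summary
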