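"""End-to-end pipeline: filter -> aggregate -> ranks -> thresholds -> report.

A single YAML/dict configuration drives every stage.  All randomness
flows from the simulation seed, and each stage's input/output row counts
are recorded in a run log together with a hash of the configuration, so
a run is auditable and two runs from the same config are byte-identical.

Config sections (all optional unless noted)::

    simulation: {...}            # SimulationConfig fields, or
    inputs: {records:, drugs:, known:}   # paths to TSVs (one of the two required)
    filters: {mw_lower: 100, mw_upper: 1000, good_cutoff: -30}
    thresholds: [{icm_max: -30}, {consensus_fraction: 0.01, protein_rank_max: 5}, ...]
    network: {formats: [graphml, sif]}
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import io as dio
from .errors import ConfigError, DataError
from .evaluate import format_comparison_table, make_comparison_table
from .network import build_network, export_network
from .prioritize import ThresholdSpec, compute_ranks, apply_threshold
from .scores import (GOOD_SCORE_CUTOFF, KnownInteractions, aggregate_best,
                     filter_drugs_by_mw, reliable_proteins)
from .synth import SimulationConfig, generate_cross_docking

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "spec_from_dict"]


def spec_from_dict(entry: dict) -> ThresholdSpec:
    """Build a ThresholdSpec from a config mapping.

    ``known_cutoff`` may be given as the compact string "worst:icm",
    "best:icm_pmf", etc.
    """
    entry = dict(entry)
    kc = entry.get("known_cutoff")
    if isinstance(kc, str):
        try:
            which, basis = kc.split(":")
        except ValueError:
            raise ConfigError(
                f"known_cutoff must look like 'worst:icm', got {kc!r}")
        entry["known_cutoff"] = (which, basis)
    elif isinstance(kc, (list, tuple)):
        entry["known_cutoff"] = tuple(kc)
    allowed = {f for f in ThresholdSpec.__dataclass_fields__}
    unknown = set(entry) - allowed
    if unknown:
        raise ConfigError(f"unknown threshold fields: {sorted(unknown)}")
    return ThresholdSpec(**entry)


def _config_hash(config: dict) -> str:
    canonical = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _load_inputs(config: dict, outdir: Path, log: dict):
    if "simulation" in config:
        sim_fields = set(SimulationConfig.__dataclass_fields__)
        unknown = set(config["simulation"]) - sim_fields
        if unknown:
            raise ConfigError(f"unknown simulation fields: {sorted(unknown)}")
        sim = SimulationConfig(**config["simulation"])
        dataset = generate_cross_docking(sim)
        records = dataset.records
        drug_table = dataset.drug_properties
        known = KnownInteractions(
            pairs=dataset.known_interactions,
            drug_status=dict(zip(drug_table["drug_id"], drug_table["status"])))
        dio.write_records(records, outdir / "records.tsv")
        dio.write_drug_table(drug_table, outdir / "drugs.tsv")
        dio.write_known(known, outdir / "known.tsv")
        log["seed"] = sim.seed
    elif "inputs" in config:
        inputs = config["inputs"]
        for key in ("records", "drugs", "known"):
            if key not in inputs:
                raise ConfigError(f"inputs section lacks {key!r}")
        records = dio.read_records(inputs["records"])
        drug_table = dio.read_drug_table(inputs["drugs"])
        known = dio.read_known(inputs["known"])
        log["seed"] = None
    else:
        raise ConfigError("config needs a 'simulation' or an 'inputs' section")
    return records, drug_table, known


def run_pipeline(config, outdir) -> dict:
    """Execute every configured stage and write all artifacts to ``outdir``.

    Returns a dict with the in-memory stage products (matrix, ranks,
    reliable proteins, per-spec predictions, comparison table, network)
    plus the run log.  Any stage failure aborts with the stage named in
    the raised error.
    """
    if not isinstance(config, dict):
        config = dio.load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"config_hash": _config_hash(config), "stages": {}}

    records, drug_table, known = _load_inputs(config, outdir, log)
    log["stages"]["inputs"] = {"records": len(records),
                               "drugs": len(drug_table),
                               "known": len(known.pairs)}

    filters = config.get("filters", {})
    mw = filter_drugs_by_mw(drug_table,
                            lower=filters.get("mw_lower", 100.0),
                            upper=filters.get("mw_upper", 1000.0))
    records = records[records["drug_id"].isin(mw.retained_set)]
    if mw.excluded.shape[0]:
        mw.excluded.to_csv(outdir / "excluded_drugs.tsv", sep="\t",
                           index=False)
    log["stages"]["mw_filter"] = {"retained_drugs": len(mw.retained),
                                  "excluded_drugs": int(mw.excluded.shape[0]),
                                  "records": len(records)}

    try:
        matrix = aggregate_best(records)
    except DataError as exc:
        raise DataError(f"aggregate stage failed: {exc}") from exc
    dio.write_matrix(matrix, outdir / "matrix")
    log["stages"]["aggregate"] = {"proteins": len(matrix.proteins),
                                  "drugs": len(matrix.drugs),
                                  "pairs": matrix.n_pairs}

    good_cutoff = filters.get("good_cutoff", GOOD_SCORE_CUTOFF)
    reliable = reliable_proteins(matrix, known, cutoff=good_cutoff)
    (outdir / "reliable_proteins.txt").write_text(
        "".join(f"{p}\n" for p in sorted(reliable)))
    log["stages"]["reliable"] = {"proteins": len(reliable)}

    ranks = compute_ranks(matrix)
    ranks.drug_rank.to_csv(outdir / "drug_rank.tsv", sep="\t",
                           index_label="protein_id")
    ranks.protein_rank_icm.to_csv(outdir / "protein_rank_icm.tsv", sep="\t",
                                  index_label="protein_id")
    ranks.protein_rank_pmf.to_csv(outdir / "protein_rank_pmf.tsv", sep="\t",
                                  index_label="protein_id")
    log["stages"]["ranks"] = {"pairs": matrix.n_pairs}

    specs = [spec_from_dict(e) for e in config.get("thresholds", [])]
    predictions: dict[str, set] = {}
    for i, spec in enumerate(specs):
        predicted = apply_threshold(spec, matrix, ranks, known)
        predictions[spec.describe()] = predicted
        _write_predictions(predicted, matrix, ranks, known,
                           outdir / f"predicted_{i:02d}.tsv")
    log["stages"]["thresholds"] = {spec.describe(): len(predictions[spec.describe()])
                                   for spec in specs}

    table = None
    if specs:
        table = make_comparison_table(matrix, ranks, known, specs)
        table.to_csv(outdir / "comparison_table.tsv", sep="\t", index=False,
                     float_format="%.6f")
        (outdir / "comparison_table.txt").write_text(
            format_comparison_table(table) + "\n")
        log["stages"]["evaluation"] = {"rows": len(table)}
    else:
        logger.info("no thresholds configured; evaluation stage skipped")

    net = None
    net_cfg = config.get("network")
    if net_cfg is not None:
        predicted_union: set = set().union(*predictions.values()) if predictions else set()
        net = build_network(matrix, known, predicted_union,
                            good_cutoff=good_cutoff)
        for fmt in net_cfg.get("formats", ["graphml"]):
            suffix = "graphml" if fmt == "graphml" else "sif"
            export_network(net, outdir / f"network.{suffix}", format=fmt)
        log["stages"]["network"] = {"nodes": net.number_of_nodes(),
                                    "edges": net.number_of_edges()}

    (outdir / "run_log.json").write_text(
        json.dumps(log, indent=2, sort_keys=True) + "\n")
    return {"matrix": matrix, "ranks": ranks, "reliable": reliable,
            "predictions": predictions, "table": table, "network": net,
            "log": log}


def _write_predictions(predicted, matrix, ranks, known, path) -> None:
    rows = []
    for p, d in sorted(predicted):
        rows.append({
            "protein_id": p, "drug_id": d,
            "icm": matrix.icm.at[p, d], "pmf": matrix.pmf.at[p, d],
            "drug_rank": ranks.drug_rank.at[p, d],
            "protein_rank_icm": ranks.protein_rank_icm.at[p, d],
            "protein_rank_pmf": ranks.protein_rank_pmf.at[p, d],
            "is_known": (p, d) in known.pairs,
        })
    columns = ["protein_id", "drug_id", "icm", "pmf", "drug_rank",
               "protein_rank_icm", "protein_rank_pmf", "is_known"]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False,
                                               float_format="%.6f")
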