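"""End-to-end pipeline: normalize -> endpoint -> fits -> bias/internalization.

Each stage either completes or raises PipelineError naming the failed stage;
outputs written before the failure are retained. Identical configuration and
seed produce byte-identical result CSVs (timestamps appear only in the log
file, never in result tables).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from .assaysim import NoiseModel, example_bias_study, simulate_concentration_response_study
from .bias import transduction_bias
from .doseresponse import ConcentrationResponse, auc_concentration_response, fit_logistic
from .internalization import quantify_internalization, surface_expression
from .io import (
    StudyConfig,
    annotate_traces,
    read_intensity_table,
    read_plate_map,
    read_plate_table,
    read_response_table,
    write_table,
)
from .traces import ratiometric

log = logging.getLogger("gpcrbias")

__all__ = ["PipelineError", "run_pipeline"]

RATIO_CHANNELS = {"bret": ("575", "460"), "deret": ("620", "520")}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


def _fits_table(fits) -> pd.DataFrame:
    rows = []
    for f in fits:
        pooled = dict(basal=f.basal, e_max=f.e_max, log_ec50=f.log_ec50, hill=f.hill)
        for p, v in pooled.items():
            rows.append((f.ligand_id, f.pathway_id, f.n_params, p, "pooled", v,
                         float("nan"), float("nan")))
        if f.summary is not None:
            for _, r in f.summary.iterrows():
                rows.append((f.ligand_id, f.pathway_id, f.n_params, r["parameter"],
                             "summary", r["mean"], r["sem"], r["n_blocks"]))
        if f.per_block is not None:
            for _, r in f.per_block.iterrows():
                for p in ("basal", "e_max", "log_ec50", "hill"):
                    rows.append((f.ligand_id, f.pathway_id, f.n_params, p,
                                 str(r["block"]), r[p], float("nan"), float("nan")))
    return pd.DataFrame(rows, columns=[
        "ligand", "pathway", "n_params", "parameter", "block", "estimate", "sem",
        "n_blocks",
    ])


def run_pipeline(config: StudyConfig) -> dict:
    """Run the stages applicable to ``config.assay_type``; return a results bundle."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = config.meta_line()
    logfile = out / "run.log"
    results: dict = {"config_sha": config.sha(), "seed": config.seed}
    stages_done: list[str] = []

    def _log(msg: str):
        log.info(msg)
        with open(logfile, "a", encoding="utf-8") as fh:
            fh.write(f"{time.strftime('%Y-%m-%dT%H:%M:%S')} {msg}\n")

    _log(f"run start: assay_type={config.assay_type} seed={config.seed} "
         f"config_sha={config.sha()}")

    def stage(name):
        def deco(fn):
            try:
                fn()
                stages_done.append(name)
                _log(f"stage {name}: ok")
            except PipelineError:
                raise
            except Exception as exc:
                _log(f"stage {name}: FAILED ({exc})")
                raise PipelineError(name, exc) from exc
        return deco

    study_holder: dict = {}

    if config.assay_type == "simulate_bias":
        @stage("simulate")
        def _():
            noise = NoiseModel(cv_multiplicative=0.05, sd_additive=0.0,
                               block_sd=0.1, seed=config.seed)
            params = example_bias_study()
            study = simulate_concentration_response_study(params, n_blocks=5, noise=noise)
            write_table(study, out / "responses.csv", meta)
            study_holder["study"] = study
            study_holder["reference"] = config.reference_ligand or "GIP"
    elif config.response_table:
        @stage("read-responses")
        def _():
            study_holder["study"] = read_response_table(config.response_table)
            study_holder["reference"] = config.reference_ligand

    if config.assay_type in ("nanobit", "bret", "deret", "fret_pka"):
        @stage("traces")
        def _():
            traces = read_plate_table(config.plate_table, baseline_end=config.baseline_end)
            design = read_plate_map(config.plate_map)
            traces = annotate_traces(traces, design)
            if config.assay_type in RATIO_CHANNELS:
                num, den = RATIO_CHANNELS[config.assay_type]
                traces = [ratiometric(t, num, den) for t in traces]
            study_holder["traces"] = traces

        @stage("concentration-response")
        def _():
            traces = study_holder["traces"]
            ligands = sorted({t.ligand for t in traces if not t.is_vehicle})
            crs, rows = [], []
            for lig in ligands:
                sub = [t for t in traces if t.ligand == lig or t.is_vehicle]
                cr = auc_concentration_response(sub, lig, config.assay_type)
                crs.append(cr)
                d = cr.data.copy()
                d.insert(0, "pathway", config.assay_type)
                d.insert(0, "ligand", lig)
                rows.append(d)
            study_holder["crs"] = crs
            write_table(pd.concat(rows, ignore_index=True),
                        out / "responses.csv", meta)

        @stage("logistic-fits")
        def _():
            fits = [fit_logistic(cr, config.n_params) for cr in study_holder["crs"]]
            table = _fits_table(fits)
            write_table(table, out / "logistic_fits.csv", meta)
            results["logistic_fits"] = table

    if config.assay_type == "htrf_endpoint":
        @stage("endpoint")
        def _():
            endpoint = read_plate_table(config.plate_table)
            design = read_plate_map(config.plate_map)
            merged = endpoint.merge(design.to_frame(), on="well", how="inner")
            rows = merged.rename(columns={"signal": "response", "conc_M": "concentration_M"})
            crs = []
            for lig, grp in rows[rows["ligand"] != "vehicle"].groupby("ligand", sort=False):
                crs.append(ConcentrationResponse(
                    str(lig), config.assay_type,
                    grp[["concentration_M", "response", "block"]].reset_index(drop=True),
                ))
            fits = [fit_logistic(cr, config.n_params) for cr in crs]
            table = _fits_table(fits)
            write_table(table, out / "logistic_fits.csv", meta)
            results["logistic_fits"] = table

    if "study" in study_holder or config.assay_type == "simulate_bias":
        @stage("bias")
        def _():
            study = study_holder["study"]
            reference = study_holder.get("reference")
            if reference is None:
                raise ValueError("reference_ligand required for bias analysis")
            bias_results, table = transduction_bias(
                study, reference_ligand=reference,
                reference_pathway=config.reference_pathway,
                comparator_pathway=config.comparator_pathway,
                n_hill=config.n_hill,
            )
            write_table(table, out / "bias_table.csv", meta)
            summary = {
                "seed": config.seed,
                "config_sha": config.sha(),
                "reference_ligand": reference,
                "reference_pathway": config.reference_pathway,
                "ligands": {
                    r.ligand_id: {
                        "delta_delta_log_R": r.mean,
                        "ci95": list(r.ci95) if r.ci95 else None,
                        "bias_factor": r.bias_factor,
                        "significant": r.significant,
                        "is_reference": r.is_reference,
                    }
                    for r in bias_results
                },
            }
            with open(out / "bias_summary.json", "w", encoding="utf-8") as fh:
                json.dump(summary, fh, indent=2, sort_keys=True)
            results["bias_table"] = table
            results["bias_results"] = bias_results

    if config.assay_type == "intensity_table":
        @stage("internalization")
        def _():
            table = read_intensity_table(config.intensity_table)
            internal = quantify_internalization(table)
            write_table(internal.drop(columns="per_block"),
                        out / "internalization.csv", meta)
            results["internalization"] = internal
            if config.reference_receptor:
                surf = surface_expression(table, config.reference_receptor)
                write_table(surf, out / "surface_expression.csv", meta)
                results["surface_expression"] = surf

    results["stages"] = stages_done
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump({"seed": config.seed, "config_sha": config.sha(),
                   "stages": stages_done}, fh, indent=2, sort_keys=True)
    _log("run complete")
    return results
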