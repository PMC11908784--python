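"""End-to-end pipeline: simulate -> call -> filter -> annotate -> burden -> stats -> enrich.

Every stage reads and writes only plain TSV/JSON artifacts under the output
directory, so stages are independently testable and reruns with the same
config and seed are byte-identical.  A JSON manifest records the config
echo, seed, version and per-stage timings.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotate import (
    GeneSetCatalog,
    PathogenicityTable,
    annotate_calls,
    burden_table,
    default_catalog,
    donor_burden,
)
from .calling import BackgroundDesign, call_variants
from .filters import FilterConfig, apply_filters
from .io import config_hash, read_table, write_table
from .simulate import SimulationConfig, simulate_cohort
from .stats import (
    SeparationError,
    UndefinedCorrelationError,
    burden_mixed_model,
    carrier_logistic,
    compare_groups,
    correlate,
    enrich_pathways,
)

log = logging.getLogger("mosaicall")

STAGES = ("simulate", "call", "filter", "annotate", "burden", "stats", "enrich")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sim_config(cfg: dict, seed: int | None) -> SimulationConfig:
    kwargs = dict(cfg.get("simulation", {}))
    for key in ("cell_types", "clone_vaf_range", "clones_per_carrier", "age_range"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    if seed is not None:
        kwargs["seed"] = seed
    return SimulationConfig(**kwargs)


def _design(cfg: dict) -> BackgroundDesign:
    pools = cfg.get("background_design")
    if pools is None:
        return BackgroundDesign()
    return BackgroundDesign({k: tuple(v) for k, v in pools.items()})


def _filter_config(cfg: dict) -> FilterConfig:
    return FilterConfig(**cfg.get("filters", {}))


def run_pipeline(config: dict, outdir, seed: int | None = None) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0)) if seed is None else int(seed)
    chash = config_hash(config)
    manifest: dict = {
        "tool": "mosaicall",
        "version": __version__,
        "seed": seed,
        "config_hash": chash,
        "config": config,
        "stages": {},
        "complete": False,
    }
    meta = {"seed": seed, "cfg_hash": chash}

    state: dict = {}
    for stage in STAGES:
        t0 = time.perf_counter()
        log.info("stage %s: start", stage)
        try:
            _STAGE_FUNCS[stage](config, state, outdir, seed, meta)
        except Exception as exc:  # noqa: BLE001 - abort with the stage name
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            _write_manifest(manifest, outdir)
            raise StageError(stage, exc) from exc
        dt = time.perf_counter() - t0
        manifest["stages"][stage] = {"status": "ok", "seconds": round(dt, 3)}
        log.info("stage %s: done in %.2fs", stage, dt)

    manifest["complete"] = True
    manifest["summary"] = state.get("summary", {})
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def _stage_simulate(config, state, outdir, seed, meta):
    inputs = config.get("inputs", {})
    if inputs.get("pileups"):
        state["pileups"] = read_table(inputs["pileups"], "pileups")
        state["metadata"] = read_table(inputs["metadata"], "metadata")
        state["sites"] = (
            read_table(inputs["sites"], "sites") if inputs.get("sites") else None
        )
        state["pathogenicity"] = (
            read_table(inputs["pathogenicity"], "pathogenicity", allow_empty=True)
            if inputs.get("pathogenicity")
            else pd.DataFrame(columns=["gene", "protein_change", "chrom", "pos",
                                       "ref", "alt", "clinvar_label", "oncokb_label"])
        )
        state["truth"] = None
        return
    sim = _sim_config(config, seed)
    bundle = simulate_cohort(sim)
    state.update(
        pileups=bundle.pileups, metadata=bundle.metadata, sites=bundle.sites,
        pathogenicity=bundle.pathogenicity, truth=bundle.truth,
    )
    write_table(bundle.pileups, outdir / "pileups.tsv", **meta)
    write_table(bundle.metadata, outdir / "metadata.tsv", **meta)
    write_table(bundle.sites, outdir / "sites.tsv", **meta)
    write_table(bundle.truth, outdir / "truth.tsv", **meta)
    write_table(bundle.pathogenicity, outdir / "pathogenicity.tsv", **meta)


def _stage_call(config, state, outdir, seed, meta):
    if state["pileups"].empty:
        raise ValueError("no sites in pileup table")
    from .calling import DEFAULT_RHO_MIN

    calls = call_variants(
        state["pileups"], state["metadata"], _design(config),
        q_cutoff=float(config.get("q_cutoff", 0.01)),
        rho_min=float(config.get("rho_min", DEFAULT_RHO_MIN)),
    )
    state["calls"] = calls
    write_table(calls, outdir / "calls.tsv", **meta)


def _stage_filter(config, state, outdir, seed, meta):
    inputs = config.get("inputs", {})
    pop_af = read_table(inputs["pop_af"], "pop_af") if inputs.get("pop_af") else None
    indels = read_table(inputs["indels"], "indels") if inputs.get("indels") else None
    fcfg = _filter_config(config)
    filtered = apply_filters(
        state["calls"], state["pileups"], fcfg, pop_af, indels,
        metadata=state["metadata"],
    )
    state["filtered"] = filtered
    state["retained"] = filtered.loc[filtered["retained"]].reset_index(drop=True)
    write_table(filtered, outdir / "filtered_calls.tsv", **meta)


def _stage_annotate(config, state, outdir, seed, meta):
    table = PathogenicityTable(state["pathogenicity"])
    catalog = state["catalog"] = _catalog(config)
    annotated = annotate_calls(state["retained"], table, catalog, sites=state["sites"])
    state["annotated"] = annotated
    write_table(annotated, outdir / "annotated_calls.tsv", **meta)


def _catalog(config) -> GeneSetCatalog:
    path = config.get("gene_set_gmt")
    if path:
        return GeneSetCatalog.from_gmt(path)
    sets = config.get("gene_sets")
    if sets:
        return GeneSetCatalog({k: set(v) for k, v in sets.items()})
    return default_catalog()


def _stage_burden(config, state, outdir, seed, meta):
    annotated, metadata = state["annotated"], state["metadata"]
    all_snv = burden_table(annotated, metadata, subset="all_SNV")
    p_snv = burden_table(annotated, metadata, subset="P_SNV", pathogenic_only=True)
    per_sample = pd.concat([all_snv, p_snv], ignore_index=True)
    per_donor = donor_burden(per_sample)
    state["burden_sample"] = per_sample
    state["burden_donor"] = per_donor
    write_table(per_sample, outdir / "burden_per_sample.tsv", **meta)
    write_table(per_donor, outdir / "burden_per_donor.tsv", **meta)


def _stage_stats(config, state, outdir, seed, meta):
    per_donor = state["burden_donor"]
    per_sample = state["burden_sample"]
    report: dict = {"seed": seed, "analyses": {}}

    focus = config.get("focus_cell_type", "microglia")
    psnv_donor = per_donor.query("subset == 'P_SNV' and cell_type == @focus")
    if psnv_donor["status"].nunique() == 2 and len(psnv_donor) >= 4:
        groups = {
            s: g["burden"].to_numpy() for s, g in psnv_donor.groupby("status")
        }
        mw = compare_groups(groups, "mann_whitney")[0]
        report["analyses"]["psnv_burden_case_vs_control"] = dataclasses.asdict(mw)
        try:
            r, p = correlate(psnv_donor["age"], psnv_donor["burden"], "spearman")
            report["analyses"]["psnv_burden_vs_age"] = {"rho": r, "p": p}
        except UndefinedCorrelationError:
            pass

    # carrier = donor with >= 1 retained pathogenic call in the focus cell type
    annotated = state["annotated"]
    meta_df = state["metadata"]
    donor_of = meta_df.set_index("sample_id")["donor_id"]
    ct_of = meta_df.set_index("sample_id")["cell_type"]
    psnv_calls = annotated.loc[
        (annotated.get("pathogenicity") == "P_SNV")
        & (annotated["sample_id"].map(ct_of) == focus)
    ]
    carriers = set(psnv_calls["sample_id"].map(donor_of))
    donors = meta_df.drop_duplicates("donor_id")[["donor_id", "status", "age", "sex"]].copy()
    donors["carrier"] = donors["donor_id"].isin(carriers)
    state["carrier_table"] = donors
    if donors["status"].nunique() == 2:
        try:
            logi = carrier_logistic(donors)
            report["analyses"]["carrier_logistic"] = dataclasses.asdict(logi)
        except SeparationError as exc:
            report["analyses"]["carrier_logistic"] = {"error": str(exc)}

    psnv_sample = per_sample.query("subset == 'P_SNV' and cell_type == @focus")
    if psnv_sample["donor_id"].nunique() >= 2 and psnv_sample["status"].nunique() == 2:
        mm = burden_mixed_model(psnv_sample)
        report["analyses"]["burden_mixed_model"] = dataclasses.asdict(mm)

    state["summary"] = {
        "n_calls": int(len(state["calls"])),
        "n_retained": int(len(state["retained"])),
        "n_psnv": int((annotated.get("pathogenicity") == "P_SNV").sum()),
        "n_carriers": int(donors["carrier"].sum()),
    }
    state["report"] = report
    with open(outdir / "stats_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)


def _stage_enrich(config, state, outdir, seed, meta):
    annotated = state["annotated"]
    sites = state["sites"]
    if sites is None or "gene" not in annotated.columns:
        state["enrichment"] = None
        return
    background = sorted(set(sites["gene"]))
    hits = sorted(set(annotated.loc[annotated["pathogenicity"] == "P_SNV", "gene"].dropna()))
    if not hits:
        state["enrichment"] = None
        (outdir / "enrichment.tsv").write_text("# mosaicall: no pathogenic hits\n")
        return
    rows = enrich_pathways(hits, state["catalog"], background)
    state["enrichment"] = rows
    write_table(rows, outdir / "enrichment.tsv", **meta)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "call": _stage_call,
    "filter": _stage_filter,
    "annotate": _stage_annotate,
    "burden": _stage_burden,
    "stats": _stage_stats,
    "enrich": _stage_enrich,
}
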