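"""End-to-end pipeline: simulate → scan → bivariate → fst → impute → stats.

Each stage writes flat tables / JSON into the output directory and the
run finishes with a provenance manifest (config hash, seeds, package and
library versions), from which the run is reproducible.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import bivariate as bv
from . import fst as fstmod
from . import impute as imp
from . import io as pio
from . import qtl
from . import stats as pstats
from .config import PipelineConfig
from .datatypes import PleiomapError
from .simulate import (PanelSimConfig, RILSimConfig, simulate_accession_panel,
                       simulate_ril_panel)

logger = logging.getLogger(__name__)


def _require(condition: bool, stage: str, what: str) -> None:
    if not condition:
        raise PleiomapError(f"stage {stage!r} requires {what}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the requested stages in order; returns the result bundle."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    state: dict = {}
    t0 = time.time()

    if "simulate" in config.stages:
        _stage_simulate(config, out, state, results)
    else:
        _stage_load(config, state)

    for name, fn in (("scan", _stage_scan), ("bivariate", _stage_bivariate),
                     ("fst", _stage_fst), ("impute", _stage_impute),
                     ("stats", _stage_stats)):
        if name in config.stages:
            t = time.time()
            fn(config, out, state, results)
            logger.info("stage %s: %.1f s", name, time.time() - t)

    manifest = {
        "config_hash": config.content_hash(),
        "seeds": config.seeds,
        "stages": list(config.stages),
        "versions": {"pleiomap": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "elapsed_s": round(time.time() - t0, 2),
    }
    pio.write_json(manifest, out / "manifest.json")
    results["manifest"] = manifest
    pio.write_json({k: v for k, v in results.items() if k != "manifest"},
                   out / "results.json")
    return results


def _stage_simulate(config, out, state, results):
    ril_cfg = RILSimConfig(**{**config.ril,
                              "seed": config.seeds["simulate_ril"]})
    gmap, panel, truth = simulate_ril_panel(ril_cfg)
    pio.write_cross(panel, out / "genotypes.csv", out / "phenotypes.csv")
    pio.write_truth(truth, out / "truth_ril.json")
    state["gmap"], state["ril"] = gmap, panel

    panel_cfg = PanelSimConfig(**{**config.panel,
                                  "seed": config.seeds["simulate_panel"]})
    snp, climate, ptruth = simulate_accession_panel(panel_cfg)
    pio.write_snp_panel_vcf(snp, out / "panel.vcf")
    pio.write_accession_metadata(snp, out / "accessions.csv")
    pio.write_climate(climate, out / "climate.csv")
    pio.write_truth(ptruth, out / "truth_panel.json")
    state["snp"], state["climate"] = snp, climate
    state["panel_cfg"] = panel_cfg
    results["simulate"] = {"n_lines": panel.n_lines,
                           "n_markers": gmap.n_markers,
                           "n_accessions": snp.n_accessions,
                           "n_snps": snp.n_snps}


def _stage_load(config, state):
    if config.genotype_csv and config.phenotype_csv:
        gmap, panel = pio.read_cross(config.genotype_csv, config.phenotype_csv)
        state["gmap"], state["ril"] = gmap, panel
    if config.snp_panel:
        state["snp"] = pio.read_snp_panel(config.snp_panel,
                                          config.accession_metadata)
    if config.climate_csv:
        state["climate"] = pio.read_climate(config.climate_csv)


def _stage_scan(config, out, state, results):
    _require("ril" in state, "scan", "a RIL cross (simulate stage or "
             "genotype/phenotype paths)")
    panel = state["ril"]
    grid = qtl.build_grid(panel.gmap, config.grid_step_cM)
    probs = qtl.genotype_probabilities(panel, grid, config.map_scale)
    state["probs"] = probs
    scan_out = {}
    traits = [c for c in panel.phenotypes.columns
              if not c.startswith("LA_")][:2]
    state["scan_traits"] = traits
    for ti, trait in enumerate(traits):
        y = panel.phenotypes[trait].to_numpy(dtype=float)
        profile = qtl.scan_trait(probs, y, trait)
        thr = qtl.permutation_threshold(
            probs, y, n_perm=config.n_perm, alpha=config.alpha,
            seed=config.seeds["scan"] + ti)
        model = qtl.stepwise_additive(probs, y, penalty=thr, trait=trait)
        state.setdefault("profiles", {})[trait] = profile
        scan_out[trait] = {
            "threshold": thr,
            "max_lod": profile.max_lod,
            "peak": profile.argmax,
            "qtls": [{"chrom": q.chrom, "pos_cM": q.pos_cM,
                      "effect": q.effect, "pve": q.pve,
                      "drop_one_lod": q.drop_one_lod} for q in model.qtls],
        }
        pd.DataFrame({"chrom": grid.chrom, "pos_cM": grid.pos,
                      "lod": profile.lod}).to_csv(
            out / f"lod_{trait}.csv", index=False)
    results["scan"] = scan_out


def _stage_bivariate(config, out, state, results):
    _require("profiles" in state and len(state.get("scan_traits", [])) == 2,
             "bivariate", "two scanned traits (scan stage)")
    t1, t2 = state["scan_traits"]
    bp = bv.sum_profiles(state["profiles"][t1], state["profiles"][t2])
    bp = bv.bivariate_interval(bp, config.interval_rule, config.interval_param)
    results["bivariate"] = {
        "traits": [t1, t2],
        "joint_peak": bp.peak,
        "interval": bp.interval,
        "rule": bp.interval_rule,
        "summed_max": float(bp.summed[bp.peak_index]),
    }
    pd.DataFrame({"chrom": bp.grid.chrom, "pos_cM": bp.grid.pos,
                  "summed_stand_lod": bp.summed}).to_csv(
        out / "bivariate_profile.csv", index=False)


def _stage_fst(config, out, state, results):
    _require("snp" in state, "fst", "a SNP panel (simulate stage or "
             "snp_panel path)")
    snp = state["snp"]
    labels = snp.labels
    mean = fstmod.genomewide_fst(snp, labels, estimator=config.fst_estimator)
    null = fstmod.permutation_null(snp, labels, K=config.permutation_K,
                                   seed=config.seeds["fst"])
    regional = fstmod.regional_fst(snp, labels,
                                   interval_bp=config.regional_interval_bp)
    out_reg = {str(c): {"fst": r.mean_fst, "n_snps": r.n_snps_used}
               for c, r in regional["clusters"].items()}
    res = {
        "estimator": config.fst_estimator,
        "genomewide_mean_fst": mean,
        "permutation_p": null.p_value,
        "permutation_K": null.K,
        "regional": out_reg,
        "regional_skipped": [str(c) for c in regional["skipped"]],
    }
    try:
        boot = fstmod.frequency_matched_bootstrap(
            snp, labels, n_snps=config.bootstrap_n_snps,
            tolerance=config.bootstrap_tolerance,
            seed=config.seeds["fst"] + 1)
        res["bootstrap_p"] = boot.p_value
    except PleiomapError as e:
        res["bootstrap_p"] = None
        res["bootstrap_note"] = str(e)
    results["fst"] = res


def _stage_impute(config, out, state, results):
    _require("snp" in state, "impute", "a SNP panel")
    snp = state["snp"]
    pcfg = state.get("panel_cfg")
    focal_chrom = pcfg.focal_chrom if pcfg else str(snp.chrom[0])
    focal_pos = pcfg.focal_pos_bp if pcfg else int(snp.pos[0])
    window = imp.extract_window(snp, focal_chrom, focal_pos,
                                config.window_half_span_bp)
    spec = imp.ClassifierSpec(seed=config.seeds["impute"])
    report = imp.kfold_cv(window, snp.labels, k=config.cv_folds, spec=spec,
                          seed=config.seeds["impute"])
    trained = imp.train_classifier(window, snp.labels, spec)
    labels_out, margins = imp.impute_labels(trained, window, snp.labels)
    pd.DataFrame({"id": snp.accession_ids, "label": labels_out,
                  "margin": margins}).to_csv(out / "imputed_labels.csv",
                                             index=False, na_rep="NA")
    results["impute"] = {
        "window_snps": int(window.X.shape[1]),
        "kfold_mean_accuracy": report.mean_accuracy,
        "selected_width": trained.width,
        "selected_regularization": trained.regularization,
    }


def _stage_stats(config, out, state, results):
    res = {}
    if "ril" in state:
        phen = state["ril"].phenotypes
        traits = [c for c in phen.columns if not c.startswith("LA_")][:2]
        if len(traits) == 2:
            r2, p, n = pstats.genetic_correlation(
                phen[traits[0]].to_numpy(), phen[traits[1]].to_numpy())
            res["genetic_correlation"] = {"traits": traits, "r2": r2,
                                          "p": p, "n": n}
    if "climate" in state:
        tests = pstats.climate_tests(state["climate"])
        ranks = pstats.rank_summary(state["climate"])
        tests.to_csv(out / "climate_tests.csv")
        ranks.to_csv(out / "climate_ranks.csv")
        res["climate"] = {
            "n_variables": len(tests),
            "n_significant_bonferroni": int(tests["significant"].sum()),
        }
    _require(bool(res), "stats", "a RIL cross or a climate table")
    results["stats"] = res
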