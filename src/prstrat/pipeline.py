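"""End-to-end pipeline: simulate/load -> QC -> hard-call -> clump -> score ->
stratify -> evaluate -> burden -> overlap-adjust, with deterministic outputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genio import (GenotypeProbabilityMatrix, hard_call, qc_filter, read_gen,
                    write_gen, write_sample, write_sumstats, read_sumstats,
                    read_sample)
from .simulate import SimulationConfig, simulate_cohort, simulate_discovery_sumstats
from .gwas import compute_pcs
from .clumping import ClumpSpec, greedy_prune
from .prs import (DEFAULT_APOE_REGION, THRESHOLD_GRID, ScoreSpec, compute_prs,
                  select_snps)
from .stratify import subset_stratum
from .evaluate import delong_ci, tail_counts, DEFAULT_TAIL_THRESHOLDS
from .burden import burden_table
from .overlap import OverlapAdjustSpec, adjusted_auc

logger = logging.getLogger(__name__)

STRATUM_KEYS = {"all": "all", "non-e4": "non_E4", "non_e4": "non_E4",
                "e3e3": "E3E3", "e4": "E4_carriers", "e4e2": "E4orE2_carriers"}

DEFAULT_CONFIG = {
    "seed": 0,
    "simulate": {},
    "qc": {"info_min": 0.8, "maf_min": 0.01},
    "hard_call_threshold": 0.9,
    "clump": {"r2_max": 0.1, "window_bp": 500_000},
    "score": {
        "thresholds": [0.001, 0.5],
        "apoe_region": list(DEFAULT_APOE_REGION),
        "missing_policy": "mean_dosage",
    },
    "strata": ["all", "e4", "e4e2", "e3e3"],
    "burden": {"thresholds": list(THRESHOLD_GRID), "cells": "means"},
    "tails": list(DEFAULT_TAIL_THRESHOLDS),
    "adjust": {"n_sims": 1000, "coefficient": 0.12, "stratum": "e3e3",
               "p_threshold": 0.5, "exclude_apoe": False},
    "n_pcs": 2,
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def validate_config(config: dict) -> dict:
    """Fill defaults and fail fast on an unusable configuration."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    if "simulate" not in config and "inputs" not in config:
        raise ValueError("config must provide either 'simulate' or 'inputs'")
    if "inputs" in config:
        inputs = config["inputs"]
        for key in ("gen", "sample", "sumstats"):
            if key not in inputs:
                raise ValueError(f"config inputs missing path '{key}'")
        cfg.pop("simulate", None)
    if cfg.get("seed") is None:
        raise ValueError("seed is required")
    for key in cfg["strata"]:
        if key not in STRATUM_KEYS:
            raise ValueError(f"unknown stratum key {key!r}")
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute all stages and write the report files under ``out_dir``.

    Returns the evaluation report as a dict.  All outputs are pure functions
    of (config, seed); two runs with the same config are byte-identical.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = {}

    # --- stage: obtain cohort + discovery sumstats -------------------------
    if "inputs" in cfg:
        gpm = read_gen(cfg["inputs"]["gen"], cfg["inputs"]["sample"],
                       cfg["inputs"].get("info"))
        samples = read_sample(cfg["inputs"]["sample"])
        sumstats = read_sumstats(cfg["inputs"]["sumstats"])
        if "ok" not in sumstats.columns:
            sumstats = sumstats.assign(ok=True)
    else:
        sim_cfg = SimulationConfig.from_dict(
            {**cfg["simulate"], "seed": cfg["simulate"].get("seed", cfg["seed"])})
        gpm, samples, model = simulate_cohort(sim_cfg)
        hard_full = hard_call(gpm, cfg["hard_call_threshold"])
        sumstats = simulate_discovery_sumstats(sim_cfg, model,
                                               (samples, hard_full))
        write_gen(gpm, out / "cohort.gen", out / "cohort.info.tsv")
        write_sample(samples, out / "cohort.sample")
        write_sumstats(sumstats.loc[sumstats["ok"]], out / "discovery.sumstats.tsv")
    counts["samples"] = len(samples)
    counts["snps_input"] = gpm.n_snps
    counts["sumstats_ok"] = int(sumstats["ok"].sum())

    # --- QC + hard-call ----------------------------------------------------
    gpm_qc = qc_filter(gpm, cfg["qc"]["info_min"], cfg["qc"]["maf_min"])
    counts["snps_post_qc"] = gpm_qc.n_snps
    hard = hard_call(gpm_qc, cfg["hard_call_threshold"])

    # --- clump -------------------------------------------------------------
    clump_spec = ClumpSpec(cfg["clump"]["r2_max"], cfg["clump"]["window_bp"])
    retained = greedy_prune(sumstats.loc[sumstats["ok"]], hard, clump_spec)
    counts["snps_retained"] = len(retained)
    (out / "retained.txt").write_text("".join(s + "\n" for s in retained))

    # --- PCs on the pruned SNP set ----------------------------------------
    keep = hard.snp_meta["snp_id"].isin(retained).to_numpy()
    from .genio import HardCallMatrix
    hard_pruned = HardCallMatrix(hard.dosage[:, keep],
                                 hard.snp_meta.loc[keep].reset_index(drop=True),
                                 hard.sample_ids)
    pcs = compute_pcs(hard_pruned, cfg["n_pcs"])

    # --- score: thresholds x region settings ------------------------------
    region = tuple(cfg["score"]["apoe_region"])
    scores = {}
    for thr in cfg["score"]["thresholds"]:
        for region_excluded in (False, True):
            spec = ScoreSpec(p_threshold=thr,
                             exclude_region=region if region_excluded else None,
                             missing_policy=cfg["score"]["missing_policy"])
            try:
                tab = compute_prs(hard, sumstats, retained, spec, pcs=pcs)
            except ValueError as exc:
                raise RuntimeError(f"stage score failed at threshold {thr} "
                                   f"(region_excluded={region_excluded}): {exc}")
            tab = tab.merge(samples, on="sample_id")
            key = f"p{thr:g}_{'excl' if region_excluded else 'incl'}"
            scores[(thr, region_excluded)] = tab
            tab.to_csv(out / f"scores_{key}.tsv", sep="\t", index=False,
                       float_format="%.6g")

    # --- stratified evaluation (Table-3-shaped grid) ----------------------
    report = {"strata": {}, "counts": counts}
    table3_rows = []
    for key in cfg["strata"]:
        stratum = STRATUM_KEYS[key]
        report["strata"][key] = {}
        for (thr, region_excluded), tab in sorted(scores.items()):
            sub = subset_stratum(tab, stratum)
            cases = sub.loc[sub["status"] == "case", "adjusted_z"].to_numpy()
            ctrls = sub.loc[sub["status"] == "control", "adjusted_z"].to_numpy()
            res = delong_ci(cases, ctrls)
            model_key = f"p{thr:g}_{'excluded' if region_excluded else 'included'}"
            report["strata"][key][model_key] = res.as_dict()
            table3_rows.append((model_key, key, res.auc, res.ci_low, res.ci_high,
                                res.n_cases, res.n_controls))
    pd.DataFrame(table3_rows, columns=["model", "stratum", "auc", "ci_low",
                                       "ci_high", "n_cases", "n_controls"]) \
        .to_csv(out / "auc_grid.tsv", sep="\t", index=False, float_format="%.6g")

    # --- burden tables (E3E3 vs other genotypes, per status class) --------
    ok_ss = sumstats.loc[sumstats["ok"]]
    region_removed = set()
    from .prs import exclude_region as _excl
    region_removed = set(_excl(hard.snp_meta, region))
    snp_sets = {}
    for thr in cfg["burden"]["thresholds"]:
        spec = ScoreSpec(p_threshold=thr, exclude_region=region)
        chosen = select_snps(ok_ss, retained, spec, hard.snp_meta)
        if chosen:
            snp_sets[float(thr)] = chosen
    geno = samples["apoe_genotype"].fillna("")
    is_e3e3 = (geno == "E3E3").to_numpy()
    determinate = geno.isin(["E2E2", "E2E3", "E2E4", "E3E3", "E3E4", "E4E4"]).to_numpy()
    is_case = (samples["status"] == "case").to_numpy()
    for label, cls_mask in (("cases", is_case), ("controls", ~is_case)):
        mask_a = is_e3e3 & cls_mask
        mask_b = determinate & ~is_e3e3 & cls_mask
        if mask_a.sum() == 0 or mask_b.sum() == 0 or not snp_sets:
            logger.warning("burden(%s): empty stratum or no SNP sets; skipped", label)
            continue
        tab = burden_table(hard, ok_ss, snp_sets, mask_a, mask_b,
                           cells=cfg["burden"]["cells"])
        tab.to_csv(out / f"burden_{label}.tsv", sep="\t", index=False,
                   float_format="%.6g")

    # --- tail counts on the adjustment stratum ---------------------------
    adj_cfg = cfg["adjust"]
    adj_stratum = STRATUM_KEYS[adj_cfg["stratum"]]
    adj_thr = float(adj_cfg["p_threshold"])
    adj_excl = bool(adj_cfg["exclude_apoe"])
    tab = scores[(adj_thr, adj_excl)]
    sub = subset_stratum(tab, adj_stratum)
    z = sub["adjusted_z"].to_numpy()
    zsd = z.std()
    z = (z - z.mean()) / zsd if zsd > 0 else z  # restandardize within stratum
    tails = tail_counts(z, sub["status"].to_numpy(), cfg["tails"])
    _write_json({str(k): v for k, v in tails.items()}, out / "tails.json")
    report["tails"] = {str(k): v for k, v in tails.items()}

    # --- overlap adjustment ----------------------------------------------
    adj_spec = OverlapAdjustSpec(n_sims=adj_cfg["n_sims"],
                                 noise_coefficient=adj_cfg["coefficient"],
                                 seed=cfg["seed"])
    stratum_samples = set(subset_stratum(samples, adj_stratum)["sample_id"])
    mask = samples["sample_id"].isin(stratum_samples).to_numpy()
    score_spec = ScoreSpec(p_threshold=adj_thr,
                           exclude_region=region if adj_excl else None,
                           missing_policy=cfg["score"]["missing_policy"])
    adj = adjusted_auc(hard, ok_ss, retained, score_spec,
                       samples["status"].to_numpy(), adj_spec, pcs=pcs,
                       sample_mask=mask)
    adj_report = {**adj.as_dict(), "coefficient": adj_cfg["coefficient"],
                  "stratum": adj_cfg["stratum"], "seed": cfg["seed"]}
    _write_json(adj_report, out / "adjusted_auc.json")
    report["adjusted_auc"] = adj_report

    # --- manifest + report -------------------------------------------------
    manifest = {
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "seed": cfg["seed"],
        "package_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "record_counts": counts,
    }
    _write_json(manifest, out / "manifest.json")
    _write_json(report, out / "report.json")
    return report
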