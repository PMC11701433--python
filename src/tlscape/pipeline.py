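"""End-to-end orchestration: gate → phenotype → compartments → TLS →
densities → contacts → signatures → survival, with a reproducible run
manifest.

A run config (YAML or dict) names the inputs and parameters; every output
lands under one run directory and the manifest echoes the full config,
package versions, per-stage row counts and wall times. Rerunning with an
identical config reproduces identical outputs (the manifest's wall times are
the only non-deterministic bytes).
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from . import __version__
from .detect import TLSDetector, calls_to_frame
from .phenotype import MarkerGater, PhenotypeAssigner, default_rules, load_rules
from .signatures import SignatureScorer, builtin_signatures, load_signatures
from .spatial import compute_densities, contact_profile
from .survival import cox_univariate, km_estimate, logrank_test, median_stratify
from .synth import (CohortConfig, SlideConfig, TLSSpec, simulate_cohort,
                    simulate_expression, simulate_slide)

DEFAULT_DENSITY_PHENOTYPES = ["CD8T", "PD1_CD8T", "TCF1_PD1_CD8T", "TIM3_PD1_CD8T",
                              "CD4T", "TFH", "Bcell", "DC", "M2TAM"]
DEFAULT_CONTACT_QUERIES = ["TCF1_PD1_CD8T", "TIM3_PD1_CD8T"]

STAGES = ("gate", "phenotype", "compartments", "tls", "densities", "contacts",
          "signatures", "survival")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    base = Path(path).parent
    for s in cfg.get("samples", []):
        for key in ("cell_table", "regions"):
            if s.get(key):
                s[key] = str((base / s[key]).resolve()) if not Path(s[key]).is_absolute() else s[key]
    for key in ("clinical", "expression", "rules_file", "signatures_file"):
        if cfg.get(key) and not Path(cfg[key]).is_absolute():
            cfg[key] = str((base / cfg[key]).resolve())
    return cfg


def validate_config(cfg: dict) -> None:
    if not cfg.get("samples"):
        raise ValueError("config lists no samples")
    for s in cfg["samples"]:
        for key in ("cell_table", "regions"):
            p = s.get(key)
            if p and not Path(p).exists():
                raise ValueError(f"input file not found: {p}")
    for key in ("clinical", "expression", "rules_file", "signatures_file"):
        p = cfg.get(key)
        if p and not Path(p).exists():
            raise ValueError(f"input file not found: {p}")


def run_pipeline(cfg: dict, outdir) -> dict:
    """Run every stage over the configured samples; returns the manifest."""
    validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": cfg, "versions": {"tlscape": __version__,
                                            "numpy": np.__version__,
                                            "pandas": pd.__version__},
                "stages": {}}
    t_all = time.perf_counter()

    def stage(name):
        manifest["stages"][name] = {"rows": 0, "wall_s": 0.0}

        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return manifest["stages"][name]

            def __exit__(self, exc_type, exc, tb):
                manifest["stages"][name]["wall_s"] = round(
                    time.perf_counter() - self.t0, 4)
                return False

        return _Timer()

    rules = load_rules(cfg["rules_file"]) if cfg.get("rules_file") else default_rules()
    thresholds = cfg.get("thresholds", {}) or {}
    det_params = cfg.get("detector", {}) or {}
    density_phenos = cfg.get("density_phenotypes", DEFAULT_DENSITY_PHENOTYPES)
    contacts_cfg = cfg.get("contacts", {}) or {}
    bin_edges = contacts_cfg.get("bin_edges", [0.0, 10.0, 20.0, 30.0])
    target = contacts_cfg.get("target", "Tumor")
    queries = contacts_cfg.get("queries", DEFAULT_CONTACT_QUERIES)

    tables = {}
    try:
        with stage("gate") as st:
            for s in cfg["samples"]:
                t = cio.read_cell_table(s["cell_table"], sample_id=s["sample_id"])
                t = MarkerGater(thresholds).fit(t).transform(t)
                tables[s["sample_id"]] = t
                st["rows"] += len(t)
    except Exception as e:
        raise PipelineError("gate", e) from e

    try:
        with stage("phenotype") as st:
            for sid, t in tables.items():
                a = PhenotypeAssigner(rules).fit(t)
                tables[sid] = a.transform(t)
                st["rows"] += len(tables[sid])
    except Exception as e:
        raise PipelineError("phenotype", e) from e

    region_sets = {}
    try:
        with stage("compartments") as st:
            for s in cfg["samples"]:
                sid = s["sample_id"]
                if s.get("regions"):
                    regions = cio.read_regions(s["regions"])
                    region_sets[sid] = regions
                    if len(regions):
                        tables[sid] = cio.assign_compartments(tables[sid], regions)
                        st["rows"] += len(tables[sid])
    except Exception as e:
        raise PipelineError("compartments", e) from e

    tls_summaries = {}
    try:
        with stage("tls") as st:
            frames, members = [], {}
            for sid, t in tables.items():
                det = TLSDetector(**det_params).fit(t)
                frame = calls_to_frame(det.calls_)
                frame.insert(0, "sample_id", sid)
                frames.append(frame)
                members[sid] = {str(c.aggregate_id): c.member_cell_ids
                                for c in det.calls_ if c.accepted}
                tls_summaries[sid] = det.summary_
                st["rows"] += len(frame)
            pd.concat(frames, ignore_index=True).to_csv(
                outdir / "tls_calls.csv", index=False)
            with open(outdir / "tls_members.json", "w") as fh:
                json.dump(members, fh, sort_keys=True, indent=1)
            pd.DataFrame([{"sample_id": k, **v} for k, v in tls_summaries.items()]
                         ).to_csv(outdir / "tls_summary.csv", index=False)
    except Exception as e:
        raise PipelineError("tls", e) from e

    try:
        with stage("densities") as st:
            frames = []
            for sid, t in tables.items():
                frames.append(compute_densities(t, region_sets.get(sid), density_phenos))
            dens = pd.concat(frames, ignore_index=True)
            dens.to_csv(outdir / "densities.csv", index=False)
            st["rows"] = len(dens)
    except Exception as e:
        raise PipelineError("densities", e) from e

    try:
        with stage("contacts") as st:
            frames = []
            for sid, t in tables.items():
                for q in queries:
                    prof = contact_profile(t, target, q, bin_edges)
                    f = prof.to_frame()
                    f["close_fraction"] = prof.close_fraction
                    frames.append(f)
            cont = pd.concat(frames, ignore_index=True)
            cont.to_csv(outdir / "contacts.csv", index=False)
            st["rows"] = len(cont)
    except Exception as e:
        raise PipelineError("contacts", e) from e

    try:
        with stage("signatures") as st:
            if cfg.get("expression"):
                matrix = cio.read_expression(cfg["expression"])
                sigs = (load_signatures(cfg["signatures_file"])
                        if cfg.get("signatures_file") else builtin_signatures())
                scorer = SignatureScorer(sigs).fit(matrix)
                scores = scorer.transform(matrix)
                scores.index.name = "sample_id"
                scores.to_csv(outdir / "signature_scores.csv")
                st["rows"] = len(scores)
    except Exception as e:
        raise PipelineError("signatures", e) from e

    try:
        with stage("survival") as st:
            if cfg.get("clinical"):
                clin = cio.read_clinical(cfg["clinical"])
                surv_cfg = cfg.get("survival", {}) or {}
                results = {}
                strat_col = surv_cfg.get("stratify_by")
                if strat_col:
                    groups = median_stratify(
                        clin.set_index("sample_id")[strat_col])
                    clin2 = clin.assign(_group=groups.reindex(clin["sample_id"]).to_numpy())
                    parts = [g for _, g in clin2.groupby("_group", sort=True)]
                    lr = logrank_test(parts)
                    results["logrank"] = {"stratify_by": strat_col, **lr}
                    km_rows = []
                    for label, g in clin2.groupby("_group", sort=True):
                        km = km_estimate(g).to_frame()
                        km.insert(0, "group", label)
                        km_rows.append(km)
                    pd.concat(km_rows, ignore_index=True).to_csv(
                        outdir / "km_curves.csv", index=False)
                cox_rows = []
                for cov in surv_cfg.get("covariates", []):
                    fit = cox_univariate(clin, cov)
                    cox_rows.append(asdict(fit))
                if cox_rows:
                    pd.DataFrame(cox_rows).to_csv(outdir / "cox_univariate.csv",
                                                  index=False)
                if results:
                    with open(outdir / "survival_tests.json", "w") as fh:
                        json.dump(results, fh, sort_keys=True, indent=1)
                st["rows"] = len(clin)
    except Exception as e:
        raise PipelineError("survival", e) from e

    manifest["wall_s_total"] = round(time.perf_counter() - t_all, 4)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1, default=str)
    return manifest


def _demo_slide_configs(seed: int) -> list[SlideConfig]:
    """Six slides: two mature-TLS-bearing, one early-only, one mixed, two
    TLS-free; every slide carries a tumor nest and lymphoid background."""
    bg = {"Tumor": 60.0, "CD8T": 120.0, "PD1_CD8T": 50.0, "TCF1_PD1_CD8T": 35.0,
          "TIM3_PD1_CD8T": 35.0, "CD4T": 120.0, "TFH": 15.0, "Treg": 25.0,
          "Bcell": 80.0, "DC": 25.0, "TAM": 60.0, "M2TAM": 30.0}
    comp_e = {"Bcell": 0.58, "CD4T": 0.20, "CD8T": 0.14, "TFH": 0.04, "other": 0.04}
    comp_p = {"Bcell": 0.57, "CD4T": 0.20, "CD8T": 0.14, "TFH": 0.04, "other": 0.03,
              "FDC21": 0.02}
    comp_s = {"Bcell": 0.57, "CD4T": 0.20, "CD8T": 0.14, "TFH": 0.04, "other": 0.03,
              "FDC21_23": 0.02}
    nest = (((1200.0, 1200.0), 220.0, 1500.0),)
    mk = lambda *specs, s: SlideConfig(
        field_width_um=1600.0, field_height_um=1600.0, background_rates=bg,
        tumor_nests=list(nest), tls_specs=list(specs), marker_flip_rate=0.0,
        seed=s)
    t = lambda c, m, comp, n=220: TLSSpec(center=c, radius_um=150.0, n_cells=n,
                                          composition=comp, maturity=m,
                                          packing_spacing_um=8.0)
    base = seed * 101
    return [
        mk(t((420.0, 420.0), "mature_secondary", comp_s),
           t((420.0, 1180.0), "early", comp_e), s=base + 0),
        mk(t((420.0, 420.0), "mature_primary", comp_p), s=base + 1),
        mk(t((420.0, 420.0), "early", comp_e), s=base + 2),
        mk(s=base + 3),
        mk(s=base + 4),
        mk(t((420.0, 420.0), "mature_secondary", comp_s),
           t((1180.0, 420.0), "mature_primary", comp_p, n=180), s=base + 5),
    ]


def simulate_demo(seed: int, outdir) -> dict:
    """Write a small synthetic dataset (slides + regions + clinical +
    expression + run config) exercising every pipeline stage; returns the
    run config dict. Deterministic in the seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = []
    truth_all = {}
    for i, scfg in enumerate(_demo_slide_configs(seed)):
        sid = f"s{i}"
        table, truths = simulate_slide(scfg)
        path = outdir / f"{sid}_cells.csv"
        cio.write_cell_table(table, path)
        # one square tumor region around the nest, stroma elsewhere
        from shapely.geometry import box
        regions = pd.DataFrame({
            "label": ["tissue", "tumor"],
            "geometry": [box(0, 0, scfg.field_width_um, scfg.field_height_um),
                         box(950, 950, 1450, 1450)]})
        rpath = outdir / f"{sid}_regions.geojson"
        cio.write_regions(regions, rpath)
        samples.append({"sample_id": sid, "cell_table": str(path.resolve()),
                        "regions": str(rpath.resolve())})
        truth_all[sid] = [{"tls_id": t.tls_id, "status": t.status,
                           "n_cells": len(t.cell_ids), "cell_ids": t.cell_ids}
                          for t in truths]
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_all, fh, sort_keys=True, indent=1)

    cohort = simulate_cohort(CohortConfig(
        n_patients=40, baseline_hazard=0.04,
        log_hr_per_covariate={"mtls_hi": -0.7},
        censor_rate=0.015,
        covariate_generators={"mtls_hi": {"dist": "bernoulli", "p": 0.5},
                              "calr_score": {"dist": "normal", "mean": 0.0, "sd": 1.0}},
        seed=seed + 17))
    cio.write_clinical(cohort, outdir / "clinical.csv")

    genes = builtin_signatures()["TLS_chemokine"]
    matrix, groups = simulate_expression(10, genes, shift=1.5,
                                         n_noise_genes=40, seed=seed + 29)
    # keep the ER-stress genes in the matrix too, unshifted
    extra, _ = simulate_expression(10, builtin_signatures()["ER_stress"],
                                   shift=0.0, n_noise_genes=0, seed=seed + 31)
    matrix = pd.concat([matrix, extra])
    cio.write_expression(matrix, outdir / "expression.csv")
    groups.rename("group").to_csv(outdir / "expression_groups.csv")

    cfg = {
        "samples": samples,
        "clinical": str((outdir / "clinical.csv").resolve()),
        "expression": str((outdir / "expression.csv").resolve()),
        "thresholds": {},
        "detector": {},
        "density_phenotypes": DEFAULT_DENSITY_PHENOTYPES,
        "contacts": {"target": "Tumor", "queries": DEFAULT_CONTACT_QUERIES,
                     "bin_edges": [0.0, 10.0, 20.0, 30.0]},
        "survival": {"stratify_by": "calr_score", "covariates": ["mtls_hi"]},
        "seed": seed,
    }
    # the YAML copy references files by name, portable next to the config
    cfg_rel = {**cfg, "clinical": "clinical.csv", "expression": "expression.csv",
               "samples": [{**s, "cell_table": Path(s["cell_table"]).name,
                            "regions": Path(s["regions"]).name}
                           for s in samples]}
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg_rel, fh, sort_keys=True)
    return cfg
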