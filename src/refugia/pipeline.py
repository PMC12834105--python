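"""Configuration-driven orchestration of the full analysis.

A single YAML/JSON config names either input files (VCF + sample CSV +
presence raster) or a ``simulate`` block of range-expansion parameters, and
the pipeline runs: simulation (optional) -> diversity (heterozygosity,
ROH) -> genetic load -> differentiation (pairwise FST, IBD Mantel) ->
spatial (variogram + kriging, refuge center, gradient tests with FDR
applied across the statistics tested in the run). Every stage writes CSV /
raster outputs plus a JSON manifest echoing the config, the seed, and
per-stage row counts; a fixed seed makes the run deterministic end to end.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import diversity as _diversity
from . import load as _load
from .differentiation import ibd_test
from .genio import derived_freqs, read_samples, read_vcf, validate_sample_table
from .raster import read_ascii_grid, write_ascii_grid
from .sim import SimConfig, simulate, write_outputs
from .spatial import (
    empirical_variogram,
    fit_variogram,
    gradient_table,
    gradient_test,
    ordinary_krige,
    refuge_center,
)

logger = logging.getLogger(__name__)

GRADIENT_STATISTICS = ("heterozygosity", "roh_count", "ratio_ns", "freq_ratio", "lof_dosage")


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        cfg = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    has_sim = "simulate" in cfg
    has_inputs = "inputs" in cfg
    if has_sim == has_inputs:
        raise ValueError("config must supply exactly one of 'simulate' or 'inputs'")
    if has_inputs:
        for key in ("vcf", "samples", "presence"):
            p = cfg["inputs"].get(key)
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"inputs.{key} missing or not found: {p}")
    cfg.setdefault("seed", 0)
    cfg.setdefault("outdir", "refugia_out")
    return cfg


def _normalize(cfg: dict) -> dict:
    return json.loads(json.dumps(cfg, sort_keys=True, default=str))


def run_all(config) -> dict:
    """Run every stage; returns (and writes) the output manifest."""
    cfg = load_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {
        "refugia_version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "config": _normalize(cfg),
        "stages": {},
        "files": {},
    }
    stage = "setup"
    try:
        # --- stage 1: data ---------------------------------------------------
        stage = "simulate" if "simulate" in cfg else "read-inputs"
        if "simulate" in cfg:
            sim_kwargs = dict(cfg["simulate"] or {})
            sim_kwargs.setdefault("seed", seed)
            if "origin" in sim_kwargs:
                sim_kwargs["origin"] = tuple(sim_kwargs["origin"])
            if "class_probs" in sim_kwargs:
                sim_kwargs["class_probs"] = tuple(sim_kwargs["class_probs"])
            sim = simulate(SimConfig(**sim_kwargs))
            gm, vt, st, presence = sim.genotypes, sim.variants, sim.samples, sim.presence
            manifest["files"].update(write_outputs(sim, outdir / "simulated"))
        else:
            gm, vt = read_vcf(cfg["inputs"]["vcf"])
            st = read_samples(cfg["inputs"]["samples"])
            presence = read_ascii_grid(cfg["inputs"]["presence"])
        validate_sample_table(st, gm)
        st = st.set_index("sample_id").loc[gm.sample_ids].reset_index()
        manifest["stages"][stage] = {"n_individuals": gm.n_individuals, "n_sites": gm.n_sites}

        # --- stage 2: diversity ---------------------------------------------
        stage = "diversity"
        het = _diversity.heterozygosity(gm)
        roh_params = dict(cfg.get("roh", {}) or {})
        lo_bp = roh_params.pop("lo_bp", 5000)
        hi_bp = roh_params.pop("hi_bp", 1e6)
        segments = _diversity.roh_table(gm, vt, **roh_params)
        summary = _diversity.roh_summary(segments, lo_bp=lo_bp, hi_bp=hi_bp,
                                         sample_ids=gm.sample_ids)
        div = summary.copy()
        div.insert(1, "heterozygosity", het)
        _write_csv(div, outdir / "diversity.csv", manifest, "diversity")
        _diversity.segments_to_bed(segments, outdir / "roh_segments.bed")
        manifest["files"]["roh_segments"] = str(outdir / "roh_segments.bed")
        manifest["stages"]["diversity"] = {"rows": len(div), "n_segments": len(segments)}

        # --- stage 3: load ----------------------------------------------------
        stage = "load"
        dfreq = derived_freqs(gm, vt)
        load_df = _load.compute_load(gm, vt, dfreq, **(cfg.get("load", {}) or {}))
        _write_csv(load_df, outdir / "load.csv", manifest, "load")
        manifest["stages"]["load"] = {"rows": len(load_df)}

        # --- stage 4: differentiation ----------------------------------------
        stage = "differentiation"
        ibd_params = dict(cfg.get("ibd", {}) or {})
        ibd_params.setdefault("n_perm", 9999)
        ibd_params.setdefault("seed", seed)
        ibd = ibd_test(gm, vt, st, **ibd_params)
        ibd.genetic.to_frame().to_csv(outdir / "fst_linearized.csv")
        ibd.geographic.to_frame().to_csv(outdir / "geographic_km.csv")
        with open(outdir / "ibd.json", "w") as fh:
            json.dump(ibd.to_dict(), fh, indent=1)
        for key in ("fst_linearized", "geographic_km", "ibd"):
            manifest["files"][key] = str(outdir / f"{key}.{'json' if key == 'ibd' else 'csv'}")
        manifest["stages"]["differentiation"] = ibd.to_dict()

        # --- stage 5: spatial -------------------------------------------------
        stage = "spatial"
        center = refuge_center(presence)
        with open(outdir / "refuge_center.json", "w") as fh:
            json.dump({"lon": center[0], "lat": center[1]}, fh, indent=1)
        manifest["files"]["refuge_center"] = str(outdir / "refuge_center.json")

        stats = {
            "heterozygosity": het,
            "roh_count": summary["roh_count"].to_numpy(float),
            "ratio_ns": load_df["ratio_ns"].to_numpy(float),
            "freq_ratio": load_df["freq_ratio"].to_numpy(float),
            "lof_dosage": load_df["lof_dosage"].to_numpy(float),
        }
        krige_cfg = dict(cfg.get("krige", {}) or {})
        family = krige_cfg.get("family", "exponential")
        n_lags = krige_cfg.get("n_lags", 12)
        krige_stats = krige_cfg.get("statistics", list(GRADIENT_STATISTICS))
        lons = st["lon"].to_numpy(float)
        lats = st["lat"].to_numpy(float)
        kriged = {}
        for name in krige_stats:
            values = stats[name]
            lag_table = empirical_variogram(lons, lats, values, n_lags=n_lags)
            model = fit_variogram(lag_table, family=family)
            pred, _var = ordinary_krige(lons, lats, values, model)
            path = outdir / f"krige_{name}.asc"
            write_ascii_grid(pred, path)
            manifest["files"][f"krige_{name}"] = str(path)
            kriged[name] = {"variogram": asdict(model)}
        results = []
        for name, values in stats.items():
            results.append(gradient_test(values, st, center, statistic=name))
        gradients = gradient_table(results)  # FDR across the run's statistics
        _write_csv(gradients, outdir / "gradient_tests.csv", manifest, "gradient_tests")
        manifest["stages"]["spatial"] = {
            "refuge_center": center,
            "kriged": kriged,
            "gradient_rows": len(gradients),
        }
    except Exception as err:
        (outdir / "FAILED").write_text(f"{stage}: {err}\n")
        if isinstance(err, PipelineError):
            raise
        raise PipelineError(stage, str(err)) from err

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return manifest


def _write_csv(df: pd.DataFrame, path: Path, manifest: dict, key: str) -> None:
    df.to_csv(path, index=False)
    manifest["files"][key] = str(path)
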