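"""End-to-end orchestration: simulate -> infer -> response -> associate
-> ldmap -> amova, with per-stage seeds derived from one root seed and a
manifest recording exactly what was run."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .amova import amova
from .genedrop import association_scan, breeding_values
from .infer import estimate_heterozygote_trajectory, infer_genotypes
from .io import (read_tables, write_tables)
from .ldmap import band_frequency_matrix, build_ld_map
from .markers import ObservationModel
from .pedigree import validate_pedigree
from .response import fit_year_correction, response_table
from .simulate import SimConfig, simulate_dse

log = logging.getLogger("dsekit")

STAGES = ("simulate", "infer", "response", "associate", "ldmap", "amova")


def stage_seeds(root_seed: int) -> dict[str, int]:
    """Derive one independent sub-2**31 seed per stochastic stage."""
    state = np.random.SeedSequence(root_seed).generate_state(len(STAGES))
    return {name: int(s % (2 ** 31)) for name, s in zip(STAGES, state)}


def run_pipeline(config: dict, out_dir: str) -> dict:
    """Run the configured stages and write all outputs under ``out_dir``.

    ``config`` keys (all optional except none): ``seed`` (root seed),
    ``simulate`` (SimConfig fields) or ``tables`` (paths to existing CSVs),
    ``observation`` (ObservationModel fields), ``response`` (``windows``),
    ``associate`` (``n_sims``), ``ldmap`` (``alpha``, ``n_perms``),
    ``amova`` (``n_perms``), ``stages`` (list of stage names to run).
    Returns a manifest dict (also written as ``manifest.json``).
    """
    os.makedirs(out_dir, exist_ok=True)
    seeds = stage_seeds(int(config.get("seed", 0)))
    enabled = config.get("stages", list(STAGES))
    manifest = {
        "version": __version__,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seeds": seeds,
        "stages": {},
        "outputs": {},
    }
    obs_model = ObservationModel(**config.get("observation", {}))

    def done(stage: str, **info) -> None:
        manifest["stages"][stage] = info
        log.info("stage %s done", stage)

    try:
        if "simulate" in enabled:
            sim_cfg = SimConfig(**{**config.get("simulate", {}),
                                   "seed": seeds["simulate"]})
            pedigree, true_geno, phenotypes, bands = simulate_dse(
                sim_cfg, obs_model)
            paths = write_tables(pedigree, phenotypes, bands, out_dir)
            tg_path = os.path.join(out_dir, "true_genotypes.csv")
            true_geno.to_csv(tg_path, index=False)
            manifest["outputs"].update(paths, true_genotypes=tg_path)
            done("simulate", n_progenitors=len(pedigree))
        elif "tables" in config:
            pedigree, phenotypes, bands = read_tables(config["tables"])
            done("load_tables", paths=config["tables"])
        else:
            raise ValueError("config must enable 'simulate' or give 'tables'")

        problems = [v for v in validate_pedigree(pedigree) if not v.warning]
        if problems:
            raise ValueError(f"invalid pedigree: {problems[:3]}")

        genotypes = None
        if "infer" in enabled:
            genotypes = infer_genotypes(pedigree, bands, obs_model)
            path = os.path.join(out_dir, "genotypes.csv")
            genotypes.to_csv(path, index=False)
            manifest["outputs"]["genotypes"] = path
            het = estimate_heterozygote_trajectory(genotypes, pedigree)
            het_path = os.path.join(out_dir, "heterozygote_trajectory.csv")
            het.to_csv(het_path)
            manifest["outputs"]["heterozygote_trajectory"] = het_path
            done("infer", n_markers=int(genotypes["marker"].nunique()))

        corrected = None
        if "response" in enabled:
            year_effects, corrected = fit_year_correction(phenotypes, pedigree)
            max_gen = int(corrected["generation"].max())
            windows = config.get("response", {}).get("windows")
            if windows is None:
                windows = [(0, 6)] + ([(7, 16)] if max_gen >= 7 else [])
            for lo, hi in windows:
                table = response_table(corrected, (int(lo), int(hi)))
                path = os.path.join(out_dir, f"response_G{lo}_G{hi}.csv")
                table.to_csv(path, index=False)
                manifest["outputs"][f"response_G{lo}_G{hi}"] = path
            done("response", year_effects=year_effects, windows=windows)

        if "associate" in enabled:
            if genotypes is None or corrected is None:
                raise ValueError("associate requires infer and response stages")
            bv = breeding_values(corrected, pedigree)
            assoc = association_scan(
                pedigree, bv, genotypes,
                n_sims=int(config.get("associate", {}).get("n_sims", 10000)),
                seed=seeds["associate"])
            path = os.path.join(out_dir, "assoc.csv")
            assoc.to_csv(path, index=False)
            manifest["outputs"]["assoc"] = path
            done("associate", n_tests=len(assoc))

        if "ldmap" in enabled:
            if genotypes is None:
                raise ValueError("ldmap requires the infer stage")
            ld_cfg = config.get("ldmap", {})
            ld = build_ld_map(genotypes, alpha=float(ld_cfg.get("alpha", 0.001)),
                              n_perms=int(ld_cfg.get("n_perms", 1000)),
                              seed=seeds["ldmap"])
            payload = {
                "groups": ld.groups,
                "orders": ld.orders,
                "r2": ld.r2.round(10).to_dict(),
                "p": ld.p.round(10).to_dict(),
                "distances": [d.to_dict(orient="records")
                              for d in ld.distances],
            }
            path = os.path.join(out_dir, "ldmap.json")
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=1, sort_keys=True)
            manifest["outputs"]["ldmap"] = path
            done("ldmap", n_groups=len(ld.groups))

        if "amova" in enabled:
            if genotypes is None:
                raise ValueError("amova requires the infer stage")
            freq = band_frequency_matrix(genotypes)
            res = amova(freq, pedigree,
                        n_perms=int(config.get("amova", {})
                                    .get("n_perms", 1000)),
                        seed=seeds["amova"])
            path = os.path.join(out_dir, "amova.csv")
            res.as_frame().to_csv(path, index=False)
            manifest["outputs"]["amova"] = path
            done("amova", percentages=res.percentages)
    except Exception as exc:
        failed_after = list(manifest["stages"])
        raise RuntimeError(
            f"pipeline failed after stages {failed_after}: {exc}") from exc
    finally:
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return manifest
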