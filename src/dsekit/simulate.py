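"""Synthetic divergent-selection-experiment generator.

Emulates the experimental design of a two-direction flowering-time selection
scheme on selfing maize lineages: each retained progenitor is selfed to
produce ``n_offspring_eval`` seeds grown as rows of 25 in a randomized block,
the ``n_selected_per_row`` most extreme plants of each row are tagged (these
are the plants whose flowering dates are recorded, 12 per progenitor by
default), and the ``n_progenitors_kept`` most extreme tagged plants of the
whole population found the next generation.  Early populations are selected
for minimal flowering time, Late populations for maximal.

Genetics: a handful of marker loci segregate from residual heterozygosity in
the founders.  Offspring genotypes follow Mendelian selfing with linkage
(recombination fractions between adjacent loci of a linkage group, free
recombination between groups; founder heterozygous loci are in coupling
phase).  A plant's flowering time (thermal time, degree-days) is

    year_effect[year] + sum over loci of (a*x + d*y) + Normal(0, residual_sd)

with x in {-1, 0, +1} the band-allele count minus one and y the
heterozygosity indicator.  Band phenotypes are observed on bulks of S2
plants through :class:`dsekit.markers.ObservationModel`.

An unselected control lineage per run is propagated by selfing a random
plant each year and phenotyped alongside, which is what identifies the year
effects in the downstream correction model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .markers import (GENOTYPE_LABELS, MarkerEffect, ObservationModel,
                      emit_band_observation)
from .pedigree import Pedigree, Progenitor


class SelectionExhausted(RuntimeError):
    """No offspring survived truncation selection in some population."""


def default_marker_loci() -> list[MarkerEffect]:
    """Six residually heterozygous loci on two linkage groups.

    Effect sizes (|a| 8-15 degree-days) match the range seen for
    flowering-time associated AFLP markers in inbred maize selection lines;
    two loci are neutral to exercise the no-signal paths.
    """
    return [
        MarkerEffect("M1", a=15.0, linkage_group="LG1",
                     recomb_fraction_to_prev=0.5),
        MarkerEffect("M2", a=0.0, linkage_group="LG1",
                     recomb_fraction_to_prev=0.05),
        MarkerEffect("M3", a=8.0, linkage_group="LG1",
                     recomb_fraction_to_prev=0.10, system="EcoRI_MspI"),
        MarkerEffect("M4", a=-10.0, linkage_group="LG2",
                     recomb_fraction_to_prev=0.5),
        MarkerEffect("M5", a=0.0, linkage_group="LG2",
                     recomb_fraction_to_prev=0.05, system="EcoRI_HpaII"),
        MarkerEffect("M6", a=0.0, d=5.0, linkage_group="LG2",
                     recomb_fraction_to_prev=0.20),
    ]


def default_year_effects(n_generations: int, start_year: int = 2000,
                         baseline: float = 1100.0) -> dict[int, float]:
    """Fixed year effects: a baseline silking thermal time plus a
    deterministic +-30 degree-day seasonal pattern."""
    pattern = [0.0, 25.0, -15.0, 30.0, -30.0, 10.0, -20.0, 15.0]
    return {start_year + i: baseline + pattern[i % len(pattern)]
            for i in range(n_generations + 1)}


@dataclass
class SimConfig:
    """Design parameters of a simulated divergent selection experiment."""

    n_generations: int = 6
    n_families: int = 2               # founder lineages per population
    n_progenitors_kept: int = 10      # per population per generation
    n_offspring_eval: int = 100       # grown as n_rows rows
    n_rows: int = 4
    n_selected_per_row: int = 3
    n_phenotyped_per_progenitor: int = 12
    marker_loci: list[MarkerEffect] = field(default_factory=default_marker_loci)
    year_effects: Optional[dict[int, float]] = None
    residual_sd: float = 25.0
    start_year: int = 2000
    background: str = "F252"
    phenotype_ceiling: Optional[float] = None  # Late plants above it cannot seed
    include_control: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_generations", "n_families", "n_progenitors_kept",
                     "n_offspring_eval", "n_rows", "n_selected_per_row",
                     "n_phenotyped_per_progenitor"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        if self.year_effects is None:
            self.year_effects = default_year_effects(
                self.n_generations, self.start_year)

    @property
    def row_size(self) -> int:
        return self.n_offspring_eval // self.n_rows


@dataclass
class _Line:
    """Internal: one live progenitor with phased marker haplotypes."""

    id: str
    parent_id: Optional[str]
    generation: int
    family: str
    population: str
    haplotypes: np.ndarray  # shape (2, n_loci), 0/1 band allele


def _founder_haplotypes(loci: list[MarkerEffect]) -> np.ndarray:
    h = np.zeros((2, len(loci)), dtype=np.int8)
    for j, locus in enumerate(loci):
        if locus.founder_state == "heterozygous":
            h[0, j] = 1  # coupling phase: all band alleles on one haplotype
        elif locus.founder_state == "fixed_present":
            h[:, j] = 1
    return h


def _gametes(haps: np.ndarray, loci: list[MarkerEffect], n: int,
             rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` gametes with linkage from a phased parent genotype."""
    n_loci = len(loci)
    choose = np.empty((n, n_loci), dtype=np.int8)
    for j, locus in enumerate(loci):
        new_group = j == 0 or locus.linkage_group != loci[j - 1].linkage_group
        if new_group:
            choose[:, j] = rng.integers(0, 2, size=n)
        else:
            cross = rng.random(n) < locus.recomb_fraction_to_prev
            choose[:, j] = np.where(cross, 1 - choose[:, j - 1],
                                    choose[:, j - 1])
    return np.take_along_axis(np.broadcast_to(haps, (n, 2, n_loci)),
                              choose[:, None, :], axis=1)[:, 0, :]


def _self_twice(haps: np.ndarray, loci: list[MarkerEffect], n: int,
                rng: np.random.Generator) -> np.ndarray:
    """Genotype allele counts of ``n`` S2 plants bred from one parent."""
    s1 = np.stack([_gametes(haps, loci, n, rng),
                   _gametes(haps, loci, n, rng)], axis=1)  # (n, 2, L)
    counts = np.empty((n, len(loci)), dtype=np.int8)
    for i in range(n):
        counts[i] = (_gametes(s1[i], loci, 1, rng)
                     + _gametes(s1[i], loci, 1, rng))[0]
    return counts


def _genetic_values(genotypes: np.ndarray, loci: list[MarkerEffect]
                    ) -> np.ndarray:
    """Sum of a*x + d*y over loci; genotypes is (n, n_loci) allele counts."""
    a = np.array([m.a for m in loci])
    d = np.array([m.d for m in loci])
    x = genotypes - 1
    y = (genotypes == 1).astype(float)
    return x @ a + y @ d


def genotype_frame(lines: list[_Line], loci: list[MarkerEffect]
                   ) -> pd.DataFrame:
    rows = []
    for ln in lines:
        if ln.population == "Control":
            continue  # control entries are seed-lot regrows, not genotyped
        counts = ln.haplotypes.sum(axis=0)
        for j, locus in enumerate(loci):
            rows.append({"progenitor_id": ln.id, "marker": locus.name,
                         "genotype": GENOTYPE_LABELS[int(counts[j])]})
    return pd.DataFrame(rows, columns=["progenitor_id", "marker", "genotype"])


def simulate_dse(config: SimConfig,
                 observation_model: Optional[ObservationModel] = None,
                 ) -> tuple[Pedigree, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run one synthetic divergent selection experiment.

    Returns ``(pedigree, true_genotypes, phenotypes, bands)``:

    * ``pedigree`` covers generations 0..n_generations for the Early and
      Late populations (plus a Control pseudo-family);
    * ``true_genotypes`` holds the simulated genotype of every progenitor at
      every marker (long form: progenitor_id, marker, genotype);
    * ``phenotypes`` records the tagged extreme plants of each progenitor's
      progeny (12 by default), measured the year the progeny was grown;
    * ``bands`` holds the dominant band states observed on bulks of S2
      plants, with scoring errors from ``observation_model``.
    """
    if observation_model is None:
        observation_model = ObservationModel()
    cfg = config
    loci = cfg.marker_loci
    rng = np.random.default_rng(cfg.seed)
    prefix = "F" if cfg.background == "F252" else "M"

    live: dict[str, list[_Line]] = {"Early": [], "Late": []}
    for pop in ("Early", "Late"):
        for f in range(cfg.n_families):
            fam = f"{prefix}{pop[0]}{f + 1}"
            live[pop].append(_Line(
                id=f"{fam}_G0_1", parent_id=None, generation=0, family=fam,
                population=pop, haplotypes=_founder_haplotypes(loci)))
    control_fam = f"{prefix}-CONTROL"
    control = (_Line(id=f"{control_fam}_G0_1", parent_id=None, generation=0,
                     family=control_fam, population="Control",
                     haplotypes=_founder_haplotypes(loci))
               if cfg.include_control else None)

    all_lines: list[_Line] = [ln for pop in live.values() for ln in pop]
    if control is not None:
        all_lines.append(control)
    pheno_rows: list[dict] = []

    for g in range(1, cfg.n_generations + 1):
        year = cfg.start_year + g
        year_eff = cfg.year_effects[year]
        for pop in ("Early", "Late"):
            candidates_pheno: list[float] = []
            candidates_meta: list[tuple[_Line, np.ndarray]] = []
            for parent in live[pop]:
                gam1 = _gametes(parent.haplotypes, loci, cfg.n_offspring_eval, rng)
                gam2 = _gametes(parent.haplotypes, loci, cfg.n_offspring_eval, rng)
                counts = (gam1 + gam2).astype(np.int8)
                pheno = (year_eff + _genetic_values(counts, loci)
                         + rng.normal(0.0, cfg.residual_sd,
                                      cfg.n_offspring_eval))
                plant_idx = 0
                for r in range(cfg.n_rows):
                    lo, hi = r * cfg.row_size, (r + 1) * cfg.row_size
                    row_order = rng.permutation(hi - lo)
                    key = pheno[lo:hi][row_order]
                    pick = np.argsort(key, kind="stable")
                    if pop == "Late":
                        pick = pick[::-1]
                    for sel in pick[:cfg.n_selected_per_row]:
                        k = lo + row_order[sel]
                        plant_idx += 1
                        pheno_rows.append({
                            "progenitor_id": parent.id,
                            "plant_index": plant_idx,
                            "year": year, "block": f"row{r + 1}",
                            "flowering_raw": np.nan,
                            "flowering_tt": pheno[k]})
                        eligible = True
                        if (pop == "Late" and cfg.phenotype_ceiling is not None
                                and pheno[k] > cfg.phenotype_ceiling):
                            eligible = False
                        if eligible:
                            candidates_pheno.append(pheno[k])
                            candidates_meta.append(
                                (parent, np.stack([gam1[k], gam2[k]])))
            if not candidates_meta:
                raise SelectionExhausted(
                    f"selection exhausted in {pop} at generation {g}")
            order = rng.permutation(len(candidates_meta))
            key = np.asarray(candidates_pheno)[order]
            pick = np.argsort(key, kind="stable")
            if pop == "Late":
                pick = pick[::-1]
            next_lines: list[_Line] = []
            fam_counter: dict[str, int] = {}
            for sel in pick[:cfg.n_progenitors_kept]:
                parent, haps = candidates_meta[order[sel]]
                fam_counter[parent.family] = fam_counter.get(parent.family, 0) + 1
                pid = f"{parent.family}_G{g}_{fam_counter[parent.family]}"
                next_lines.append(_Line(
                    id=pid, parent_id=parent.id, generation=g,
                    family=parent.family, population=pop,
                    haplotypes=haps.astype(np.int8)))
            next_lines.sort(key=lambda ln: ln.id)
            live[pop] = next_lines
            all_lines.extend(next_lines)
        if control is not None:
            # Control plants are S2 seed regrown from the *initial* seed lot
            # every year (no drift accumulates along the control entries);
            # the pedigree chain only carries the per-year record structure.
            n = cfg.n_phenotyped_per_progenitor
            counts = _self_twice(control.haplotypes, loci, n, rng)
            pheno = (year_eff + _genetic_values(counts, loci)
                     + rng.normal(0.0, cfg.residual_sd, n))
            for m in range(n):
                pheno_rows.append({
                    "progenitor_id": control.id, "plant_index": m + 1,
                    "year": year, "block": "row1",
                    "flowering_raw": np.nan, "flowering_tt": pheno[m]})
            control = _Line(
                id=f"{control_fam}_G{g}_1", parent_id=control.id,
                generation=g, family=control_fam, population="Control",
                haplotypes=control.haplotypes)
            all_lines.append(control)

    pedigree = Pedigree(Progenitor(ln.id, ln.parent_id, ln.generation,
                                   ln.family, ln.population, cfg.background)
                        for ln in all_lines)
    true_genotypes = genotype_frame(all_lines, loci)
    phenotypes = pd.DataFrame(
        pheno_rows, columns=["progenitor_id", "plant_index", "year", "block",
                             "flowering_raw", "flowering_tt"])
    bands = _observe_bands(all_lines, loci, observation_model, rng)
    return pedigree, true_genotypes, phenotypes, bands


def _observe_bands(lines: list[_Line], loci: list[MarkerEffect],
                   model: ObservationModel, rng: np.random.Generator
                   ) -> pd.DataFrame:
    rows = []
    for ln in sorted(lines, key=lambda x: (x.generation, x.id)):
        if ln.population == "Control":
            continue  # only selected progenitors are genotyped
        counts = ln.haplotypes.sum(axis=0)
        for j, locus in enumerate(loci):
            obs = emit_band_observation(int(counts[j]), model, rng,
                                        systems=(locus.system,))
            rows.append({"progenitor_id": ln.id, "marker": locus.name,
                         "system": locus.system,
                         "state": float(obs[locus.system])})
    return pd.DataFrame(rows, columns=["progenitor_id", "marker", "system",
                                       "state"])
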