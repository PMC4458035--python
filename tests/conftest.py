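"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from dsekit.markers import ObservationModel
from dsekit.pedigree import Pedigree, Progenitor


def chain_pedigree(n_generations: int, family: str = "FL1",
                   population: str = "Late") -> Pedigree:
    """A single selfing lineage G0..Gn (one progenitor per generation)."""
    progenitors = [Progenitor(f"{family}_G0", None, 0, family, population,
                              "F252")]
    for g in range(1, n_generations + 1):
        progenitors.append(Progenitor(f"{family}_G{g}", f"{family}_G{g-1}",
                                      g, family, population, "F252"))
    return Pedigree(progenitors)


@pytest.fixture
def two_family_pedigree() -> Pedigree:
    """Ten progenitors in two families, branched like a small DSE pedigree."""
    rows = [
        ("FE1_G0", None, 0, "FE1", "Early"),
        ("FE1_G1a", "FE1_G0", 1, "FE1", "Early"),
        ("FE1_G1b", "FE1_G0", 1, "FE1", "Early"),
        ("FE1_G2a", "FE1_G1a", 2, "FE1", "Early"),
        ("FE1_G2b", "FE1_G1a", 2, "FE1", "Early"),
        ("FL1_G0", None, 0, "FL1", "Late"),
        ("FL1_G1", "FL1_G0", 1, "FL1", "Late"),
        ("FL1_G2a", "FL1_G1", 2, "FL1", "Late"),
        ("FL1_G2b", "FL1_G1", 2, "FL1", "Late"),
        ("FL1_G3", "FL1_G2a", 3, "FL1", "Late"),
    ]
    return Pedigree(Progenitor(i, p, g, f, pop, "F252")
                    for i, p, g, f, pop in rows)


def random_pedigree(rng: np.random.Generator, n: int) -> Pedigree:
    """A random forest of up to ``n`` progenitors (single founder or two)."""
    n_founders = 1 if n < 4 else int(rng.integers(1, 3))
    progenitors = []
    nodes: list[tuple[str, int]] = []
    for f in range(n_founders):
        pid = f"F{f}_G0"
        progenitors.append(Progenitor(pid, None, 0, f"F{f}", "Early", "F252"))
        nodes.append((pid, 0))
    while len(progenitors) < n:
        parent, g = nodes[int(rng.integers(0, len(nodes)))]
        pid = f"P{len(progenitors)}"
        progenitors.append(Progenitor(pid, parent, g + 1,
                                      progenitors[0].family, "Early", "F252"))
        nodes.append((pid, g + 1))
    return Pedigree(progenitors)


def brute_force_locus_loglik(pedigree: Pedigree, band: dict,
                             model: ObservationModel) -> float:
    """Exhaustive maximum over all 3^n genotype configurations.

    Independent oracle for the max-product DP: enumerates every assignment
    and returns the best total (transmission + observation) log-likelihood.
    """
    from dsekit.infer import band_observation_loglik
    from dsekit.markers import SELFING_TRANSITION

    order = pedigree.topological_order()
    ids = [p.id for p in order]
    idx = {pid: k for k, pid in enumerate(ids)}
    edges = [(idx[p.parent_id], idx[p.id]) for p in order
             if p.parent_id is not None]
    obs = np.array([[band_observation_loglik(g, band.get(pid), model)
                     for g in range(3)] for pid in ids])
    with np.errstate(divide="ignore"):
        log_t = np.log(SELFING_TRANSITION)
    best = -math.inf
    for config in itertools.product(range(3), repeat=len(ids)):
        ll = sum(obs[k, config[k]] for k in range(len(ids)))
        for a, b in edges:
            ll += log_t[config[a], config[b]]
        best = max(best, ll)
    return best


def enumerate_bulk_band_probability(selfings: int, bulk_size: int,
                                    independent_s1: bool) -> float:
    """Exact P(band in bulk | progenitor Bb) by exhaustive enumeration.

    Enumerates gamete pairs at every selfing step with their probabilities;
    independent of the closed-form expression used by the package.
    """
    def offspring_dist(genotype: int) -> dict[int, float]:
        out: dict[int, float] = {}
        alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[genotype]
        for a in alleles:
            for b in alleles:
                out[a + b] = out.get(a + b, 0.0) + 0.25
        return out

    def distribution_after(genotype: int, steps: int) -> dict[int, float]:
        dist = {genotype: 1.0}
        for _ in range(steps):
            nxt: dict[int, float] = {}
            for g, p in dist.items():
                for g2, q in offspring_dist(g).items():
                    nxt[g2] = nxt.get(g2, 0.0) + p * q
            dist = nxt
        return dist

    if independent_s1 or selfings < 2:
        dist = distribution_after(1, selfings)
        p_bandless = dist.get(0, 0.0)
        return 1.0 - p_bandless ** bulk_size
    total = 0.0
    for s1, p1 in distribution_after(1, 1).items():
        dist2 = distribution_after(s1, selfings - 1)
        total += p1 * dist2.get(0, 0.0) ** bulk_size
    return 1.0 - total
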