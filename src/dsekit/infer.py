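"""Maximum-likelihood genotype reconstruction from dominant band phenotypes.

Dominant AFLP/M-SAP bands do not distinguish ``BB`` from ``Bb``; pedigree
information does.  For one marker, the joint likelihood of a genotype
assignment over all progenitors of a selfing pedigree factorizes over the
forest:

    L = prod_founders prior(g) * prod_edges T(g_parent -> g_child)
        * prod_nodes P(observed band | g)

with ``T`` the Mendelian selfing transition (``BB -> BB``, ``bb -> bb``,
``Bb -> 1/4 BB, 1/2 Bb, 1/4 bb``; no reversion) and the observation term
given by the bulk model of :mod:`dsekit.markers`.  Because each node has a
single parent, the maximizing assignment is found exactly by max-product
dynamic programming on each tree (a Viterbi-style upward pass followed by a
downward backtrace) — no heuristic search is needed.

Ties between equally likely assignments are broken deterministically:
prefer fewer heterozygotes overall, then the smaller genotype under the
order ``bb < Bb < BB`` at each node, visited root-down in pedigree order.
The founder prior is uniform and therefore dropped from the reported
log-likelihood (it shifts every assignment equally).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .markers import GENOTYPE_LABELS, ObservationModel, SELFING_TRANSITION
from .pedigree import Pedigree

_NEG_INF = float("-inf")


class UninformativeLocusError(ValueError):
    """Every band observation at the locus is missing."""


def _log(p: float) -> float:
    return math.log(p) if p > 0.0 else _NEG_INF


def band_observation_loglik(genotype: int, observed_state: Optional[float],
                            model: ObservationModel) -> float:
    """log P(observed band state | progenitor genotype) under the bulk model.

    ``observed_state`` is 1 (present), 0 (absent) or None/NaN (missing,
    contributing log 1 = 0).
    """
    if observed_state is None or (isinstance(observed_state, float)
                                  and math.isnan(observed_state)):
        return 0.0
    p_present = model.p_observed_present(genotype)
    return _log(p_present if observed_state else 1.0 - p_present)


@dataclass
class LocusInference:
    """ML genotype assignment for one marker over a whole pedigree."""

    marker: str
    genotypes: dict[str, int]          # progenitor id -> 0/1/2
    loglik: float                      # transmission + observation terms
    obs_loglik: dict[str, float] = field(default_factory=dict)

    def labels(self) -> dict[str, str]:
        return {pid: GENOTYPE_LABELS[g] for pid, g in self.genotypes.items()}


def infer_locus_genotypes(pedigree: Pedigree,
                          band: Mapping[str, Optional[float]],
                          observation_model: ObservationModel,
                          transmission: Optional[np.ndarray] = None,
                          marker: str = "",
                          ) -> LocusInference:
    """Exact ML genotype assignment for one marker.

    ``band`` maps progenitor id to observed state (1/0/NaN); ids absent from
    the mapping count as missing.  Raises
    :class:`UninformativeLocusError` when no observation is present.
    """
    if transmission is None:
        transmission = SELFING_TRANSITION
    log_t = np.array([[_log(transmission[i, j]) for j in range(3)]
                      for i in range(3)])

    def obs(pid: str) -> Optional[float]:
        v = band.get(pid)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return float(v)

    if not any(obs(pid) is not None for pid in pedigree.ids):
        raise UninformativeLocusError(
            f"uninformative locus {marker!r}: all observations missing")

    obs_ll = {pid: np.array([band_observation_loglik(g, obs(pid),
                                                     observation_model)
                             for g in range(3)])
              for pid in pedigree.ids}

    genotypes: dict[str, int] = {}
    total = 0.0
    for tree in pedigree.trees():
        # Upward pass: up[pid][s] = (best loglik, -n_het) of the subtree
        # rooted at pid given genotype s at pid.
        up: dict[str, list[tuple[float, float]]] = {}
        for node in reversed(tree):
            vals = []
            for s in range(3):
                ll = obs_ll[node.id][s]
                het = -1.0 if s == 1 else 0.0
                for child in pedigree.children(node.id):
                    best = (_NEG_INF, 0.0)
                    for cs in range(3):
                        cand = (log_t[s, cs] + up[child.id][cs][0],
                                up[child.id][cs][1])
                        if cand > best:
                            best = cand
                    ll += best[0]
                    het += best[1]
                vals.append((ll, het))
            up[node.id] = vals
        # Downward backtrace, preferring smaller genotype codes on ties.
        root = tree[0]
        state = {root.id: int(np.lexsort(
            (np.arange(3), [-v[1] for v in up[root.id]],
             [-v[0] for v in up[root.id]]))[0])}
        for node in tree:
            s = state[node.id]
            genotypes[node.id] = s
            for child in pedigree.children(node.id):
                best, best_cs = (_NEG_INF, 0.0), 0
                for cs in range(3):
                    cand = (log_t[s, cs] + up[child.id][cs][0],
                            up[child.id][cs][1])
                    if cand > best:
                        best, best_cs = cand, cs
                state[child.id] = best_cs
        total += up[root.id][state[root.id]][0]

    obs_contrib = {pid: float(obs_ll[pid][genotypes[pid]])
                   for pid in genotypes}
    return LocusInference(marker=marker, genotypes=genotypes, loglik=total,
                          obs_loglik=obs_contrib)


def infer_genotypes(pedigree: Pedigree, bands: pd.DataFrame,
                    observation_model: Optional[ObservationModel] = None,
                    ) -> pd.DataFrame:
    """Infer genotypes for every marker of a long-form band table.

    Returns a long-form frame ``progenitor_id, marker, genotype, loglik``
    where ``loglik`` is the per-entry observation contribution (the marker's
    total also includes transmission terms).
    """
    if observation_model is None:
        observation_model = ObservationModel()
    rows = []
    for marker, sub in bands.groupby("marker", sort=True):
        column = dict(zip(sub["progenitor_id"], sub["state"]))
        inf = infer_locus_genotypes(pedigree, column, observation_model,
                                    marker=str(marker))
        labels = inf.labels()
        for p in pedigree.topological_order():
            rows.append({"progenitor_id": p.id, "marker": marker,
                         "genotype": labels[p.id],
                         "loglik": inf.obs_loglik[p.id]})
    return pd.DataFrame(rows, columns=["progenitor_id", "marker", "genotype",
                                       "loglik"])


def profile_error_rates(pedigree: Pedigree, bands: pd.DataFrame,
                        grid: Optional[np.ndarray] = None,
                        ) -> tuple[float, float, pd.DataFrame]:
    """Grid-profile the scoring error rates fp and fn.

    Scores each (fp, fn) pair on the grid by the summed best-assignment
    log-likelihood across all markers and returns the maximizing pair with
    the full profile (columns fp, fn, loglik).  No external calibration
    data exist for the band-scoring error rates, so this profiles them out
    of the same likelihood the genotypes are inferred from.
    """
    if grid is None:
        grid = np.array([0.005, 0.01, 0.02, 0.05, 0.1])
    rows = []
    for fp in grid:
        for fn in grid:
            model = ObservationModel(fp=float(fp), fn=float(fn))
            total = 0.0
            for marker, sub in bands.groupby("marker", sort=True):
                column = dict(zip(sub["progenitor_id"], sub["state"]))
                try:
                    total += infer_locus_genotypes(
                        pedigree, column, model, marker=str(marker)).loglik
                except UninformativeLocusError:
                    continue
            rows.append({"fp": float(fp), "fn": float(fn), "loglik": total})
    profile = pd.DataFrame(rows)
    best = profile.loc[profile["loglik"].idxmax()]
    return float(best["fp"]), float(best["fn"]), profile


def filter_non_mendelian(bands: pd.DataFrame, pedigree: Pedigree
                         ) -> tuple[list[str], list[dict]]:
    """Discard markers whose only variation is a non-transmitted singleton.

    A band state carried by exactly one progenitor, absent from its parent
    and from every observed offspring, is indistinguishable from a scoring
    artefact and is discarded.  A singleton in a terminal progenitor (no
    observed offspring) cannot be checked and is retained with an
    ``unconfirmed`` flag in the log.

    Returns ``(retained_markers, log)`` where each log record has keys
    ``marker, action, reason`` (and ``progenitor_id`` for singletons).
    """
    matrix = bands.pivot_table(index="progenitor_id", columns="marker",
                               values="state", aggfunc="first", dropna=False)
    retained, log = [], []
    for marker in matrix.columns:
        col = matrix[marker].dropna()
        counts = col.value_counts()
        if len(counts) == 2 and counts.min() == 1:
            minority_state = counts.idxmin()
            pid = col[col == minority_state].index[0]
            if pid not in pedigree:
                retained.append(marker)
                continue
            parent_id = pedigree[pid].parent_id
            parent_state = (col.get(parent_id) if parent_id is not None
                            else None)
            child_states = [col[c.id] for c in pedigree.children(pid)
                            if c.id in col.index]
            if parent_state == minority_state or minority_state in child_states:
                retained.append(marker)
                log.append({"marker": marker, "action": "retained",
                            "reason": "variant transmitted",
                            "progenitor_id": pid})
            elif not child_states:
                retained.append(marker)
                log.append({"marker": marker, "action": "retained",
                            "reason": "unconfirmed terminal singleton",
                            "progenitor_id": pid})
            else:
                log.append({"marker": marker, "action": "discarded",
                            "reason": "non-Mendelian singleton",
                            "progenitor_id": pid})
        else:
            retained.append(marker)
    return retained, log


def estimate_heterozygote_trajectory(genotypes: pd.DataFrame,
                                     pedigree: Pedigree) -> pd.Series:
    """Per-generation frequency of heterozygotes among segregating markers.

    ``genotypes`` is long form (progenitor_id, marker, genotype).  A marker
    is segregating if at least two distinct genotypes occur across the
    pedigree.  The frequency at generation g is the fraction of
    (progenitor, segregating marker) pairs called ``Bb``.  Residual
    heterozygosity is expected to halve per generation under selfing.
    """
    seg = [m for m, sub in genotypes.groupby("marker")
           if sub["genotype"].nunique() > 1]
    if not seg:
        return pd.Series(dtype=float, name="het_frequency")
    sub = genotypes[genotypes["marker"].isin(seg)].copy()
    sub["generation"] = [pedigree[pid].generation
                         for pid in sub["progenitor_id"]]
    out = (sub.assign(het=sub["genotype"] == "Bb")
              .groupby("generation")["het"].mean())
    out.name = "het_frequency"
    return out
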