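"""Linkage-disequilibrium map building from pedigree band frequencies.

LD between two dominant markers is the squared Pearson correlation (r2)
between their per-progenitor band frequencies (0, 0.5 or 1 for bb, Bb, BB).
In a selfing pedigree the mating-system component of LD is homogeneous
across the genome, so r2 decays with genetic distance and can be used to
build a marker map the way recombination fractions are in conventional
linkage mapping:

1. permutation P-values of every pair (permuting genotypes between
   progenitors) define a significance graph whose connected components are
   the linkage groups;
2. within a group, markers are ordered by a rank criterion: under the true
   order, pairs separated by the same number of intervals should have
   similar LD ranks, so the order minimizing the summed per-offset rank
   variance is retained (exhaustive for small groups, hill climbing with
   swaps and segment reversals otherwise);
3. map distances between adjacent markers are d = -log(r2) (natural log),
   treated as additive along the order.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import rankdata

BAND_FREQUENCY = {"bb": 0.0, "Bb": 0.5, "BB": 1.0}


def band_frequency_vector(genotypes: pd.DataFrame, marker: str) -> pd.Series:
    """Per-progenitor band frequency (0 / 0.5 / 1) of one marker."""
    sub = genotypes[genotypes["marker"] == marker]
    if sub.empty:
        raise KeyError(f"no genotypes for marker {marker!r}")
    out = sub.set_index("progenitor_id")["genotype"].map(BAND_FREQUENCY)
    out.name = marker
    return out


def band_frequency_matrix(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Progenitor x marker matrix of band frequencies."""
    wide = genotypes.pivot_table(index="progenitor_id", columns="marker",
                                 values="genotype", aggfunc="first",
                                 dropna=False)
    return wide.apply(lambda c: c.map(BAND_FREQUENCY))


def compute_r2(freq: pd.DataFrame) -> pd.DataFrame:
    """Pairwise r2 between marker frequency vectors (pairwise-complete).

    Markers without variance get missing entries (with a warning): their
    correlation with anything is undefined.
    """
    if freq.shape[1] < 2:
        raise ValueError("need at least two markers")
    constant = [m for m in freq.columns if freq[m].dropna().nunique() <= 1]
    if constant:
        warnings.warn(f"zero-variance marker(s) {constant}: r2 undefined",
                      UserWarning, stacklevel=2)
    r2 = freq.corr(method="pearson", min_periods=2) ** 2
    np.fill_diagonal(r2.values, 1.0)
    for m in constant:
        r2.loc[m, :] = np.nan
        r2.loc[:, m] = np.nan
        r2.loc[m, m] = 1.0
    return r2


def ld_permutation_test(freq: pd.DataFrame, n_perms: int = 1000,
                        seed: int = 0) -> pd.DataFrame:
    """Permutation P-values for every marker pair.

    For each pair, one vector is permuted across progenitors ``n_perms``
    times; ``p = (1 + #{r2_perm >= r2_obs}) / (n_perms + 1)`` (add-one, so
    p is never 0).  Pairs with undefined r2 get missing P-values.
    """
    if n_perms < 100:
        raise ValueError("n_perms must be >= 100")
    rng = np.random.default_rng(seed)
    markers = list(freq.columns)
    r2_obs = compute_r2(freq)
    p = pd.DataFrame(np.nan, index=markers, columns=markers)
    np.fill_diagonal(p.values, 0.0)
    for i, j in itertools.combinations(range(len(markers)), 2):
        pair = freq.iloc[:, [i, j]].dropna()
        obs = r2_obs.iloc[i, j]
        if len(pair) < 3 or np.isnan(obs):
            continue
        xi = pair.iloc[:, 0].to_numpy(dtype=float)
        xj = pair.iloc[:, 1].to_numpy(dtype=float)
        perms = rng.permuted(np.tile(xj, (n_perms, 1)), axis=1)
        r2_perm = _corr_with(xi, perms) ** 2
        count = np.count_nonzero(r2_perm >= obs - 1e-12)
        p.iloc[i, j] = p.iloc[j, i] = (1.0 + count) / (n_perms + 1.0)
    return p


def _corr_with(x: np.ndarray, rows: np.ndarray) -> np.ndarray:
    xc = x - x.mean()
    rc = rows - rows.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc ** 2).sum() * (rc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, rc @ xc / denom, 0.0)


def form_linkage_groups(p: pd.DataFrame, alpha: float = 0.001
                        ) -> list[list[str]]:
    """Single-linkage components of the graph with edges p <= alpha."""
    markers = list(p.columns)
    adj = (p.to_numpy() <= alpha).astype(int)
    np.fill_diagonal(adj, 1)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups = [[] for _ in range(n_comp)]
    for m, lab in zip(markers, labels):
        groups[lab].append(m)
    groups.sort(key=lambda g: (-len(g), g[0]))
    return groups


def _rank_matrix(r2: np.ndarray) -> np.ndarray:
    """Rank the off-diagonal r2 values (average ranks on ties)."""
    iu = np.triu_indices_from(r2, k=1)
    ranks = rankdata(r2[iu])
    out = np.zeros_like(r2)
    out[iu] = ranks
    return out + out.T


def rank_dispersion(order: Sequence[int], ranks: np.ndarray) -> float:
    """Ordering objective: summed variance of LD ranks per interval offset.

    Under a correct order, marker pairs separated by the same number of
    intervals should have similar LD, hence similar ranks; the best order
    minimizes this statistic.
    """
    m = len(order)
    total = 0.0
    idx = np.asarray(order)
    for k in range(1, m):
        vals = ranks[idx[:-k], idx[k:]]
        if len(vals) > 1:
            total += float(np.var(vals))
    return total


def order_markers(group: Sequence[str], r2: pd.DataFrame,
                  max_exhaustive: int = 8, n_starts: int = 20,
                  seed: int = 0) -> list[str]:
    """Order the markers of one linkage group by the rank criterion.

    Exhaustive search over all orders (up to reversal) for groups of up to
    ``max_exhaustive`` markers; seeded multi-start hill climbing with
    pairwise swaps and segment reversals beyond that.  The returned order
    is canonicalized so that its first marker label sorts before its last.
    """
    group = list(group)
    m = len(group)
    if m < 2:
        return group
    sub = r2.loc[group, group].to_numpy(dtype=float)
    if np.isnan(sub).any():
        raise ValueError(f"incomplete LD within group {group}")
    if m == 2:
        return _canonical(group)
    ranks = _rank_matrix(sub)
    if m <= max_exhaustive:
        best, best_obj = None, np.inf
        for perm in itertools.permutations(range(m)):
            if perm[0] > perm[-1]:
                continue  # each order is equivalent to its reversal
            obj = rank_dispersion(perm, ranks)
            if obj < best_obj - 1e-12:
                best, best_obj = perm, obj
        idx = list(best)
    else:
        rng = np.random.default_rng(seed)
        best, best_obj = None, np.inf
        for _ in range(n_starts):
            idx0 = list(rng.permutation(m))
            idx0, obj = _hill_climb(idx0, ranks)
            if obj < best_obj - 1e-12:
                best, best_obj = idx0, obj
        idx = best
    return _canonical([group[i] for i in idx])


def _hill_climb(order: list[int], ranks: np.ndarray
                ) -> tuple[list[int], float]:
    m = len(order)
    obj = rank_dispersion(order, ranks)
    improved = True
    while improved:
        improved = False
        for i in range(m - 1):
            for j in range(i + 1, m):
                # segment reversal (includes the i-j swap when j = i + 1)
                cand = order[:i] + order[i:j + 1][::-1] + order[j + 1:]
                c_obj = rank_dispersion(cand, ranks)
                if c_obj < obj - 1e-12:
                    order, obj, improved = cand, c_obj, True
        for i in range(m):
            for j in range(m):
                if abs(i - j) < 2:
                    continue
                cand = order.copy()
                cand[i], cand[j] = cand[j], cand[i]
                c_obj = rank_dispersion(cand, ranks)
                if c_obj < obj - 1e-12:
                    order, obj, improved = cand, c_obj, True
    return order, obj


def _canonical(order: list[str]) -> list[str]:
    return order if order[0] <= order[-1] else order[::-1]


def map_distances(order: Sequence[str], r2: pd.DataFrame) -> pd.DataFrame:
    """Additive -log(r2) distances between adjacent ordered markers.

    Returns one row per marker with its cumulative position; an adjacent
    r2 of zero yields an infinite distance and a ``split_suggested`` flag
    (the pair shows no residual association and should arguably be two
    groups).
    """
    rows = [{"marker": order[0], "d_to_prev": 0.0, "position": 0.0,
             "split_suggested": False}]
    pos = 0.0
    for a, b in zip(order[:-1], order[1:]):
        val = float(r2.loc[a, b])
        with np.errstate(divide="ignore"):
            d = float(-np.log(val)) if val > 0 else float("inf")
        pos += d
        rows.append({"marker": b, "d_to_prev": d, "position": pos,
                     "split_suggested": not np.isfinite(d)})
    return pd.DataFrame(rows, columns=["marker", "d_to_prev", "position",
                                       "split_suggested"])


@dataclass
class LDMap:
    """A full LD map: r2 and P matrices, groups, orders and positions."""

    r2: pd.DataFrame
    p: pd.DataFrame
    groups: list[list[str]]
    orders: list[list[str]] = field(default_factory=list)
    distances: list[pd.DataFrame] = field(default_factory=list)


def build_ld_map(genotypes: pd.DataFrame, alpha: float = 0.001,
                 n_perms: int = 1000, seed: int = 0) -> LDMap:
    """Run the whole LD pipeline on a long-form genotype table."""
    freq = band_frequency_matrix(genotypes)
    variable = [m for m in freq.columns if freq[m].dropna().nunique() > 1]
    freq = freq[variable]
    r2 = compute_r2(freq)
    p = ld_permutation_test(freq, n_perms=n_perms, seed=seed)
    groups = form_linkage_groups(p, alpha=alpha)
    orders, dists = [], []
    for g in groups:
        order = order_markers(g, r2, seed=seed)
        orders.append(order)
        dists.append(map_distances(order, r2))
    return LDMap(r2=r2, p=p, groups=groups, orders=orders, distances=dists)
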