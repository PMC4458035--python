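"""Marker-effect estimation with pedigree gene-dropping significance tests.

A marker's additive (a) and dominance (d) effects on flowering time are
estimated by regressing progenitor breeding values (per-generation-centered
mean corrected phenotypes) on the indicator pair (x, y), with
(x, y) = (-1, 0) for the band-absent homozygote, (0, 1) for the
heterozygote and (1, 0) for the band homozygote.

Ordinary regression P-values are meaningless here: genotypes flow through a
pedigree, so progenitors are not exchangeable.  The null distribution is
built by *gene dropping* — founders are set heterozygous and alleles are
dropped through the pedigree under Mendelian selfing transmission (no
reversion); each simulated genotype matrix is refitted against the same
observed breeding values.  Empirical P-values use the add-one rule
(p is never exactly zero) and two-sided |a|, |d| comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .markers import GENOTYPE_CODES
from .pedigree import Pedigree

SCOPES = ("global", "within_Early", "within_Late")


def encode_genotype(genotype: Optional[str]) -> tuple[float, float]:
    """Map a genotype label to the (x, y) regression indicators."""
    if genotype is None or (isinstance(genotype, float) and np.isnan(genotype)):
        return (float("nan"), float("nan"))
    code = GENOTYPE_CODES.get(genotype)
    if code is None:
        raise ValueError(f"unknown genotype {genotype!r}")
    return (float(code - 1), 1.0 if code == 1 else 0.0)


def breeding_values(corrected: pd.DataFrame, pedigree: Pedigree
                    ) -> pd.DataFrame:
    """Per-progenitor breeding values G and per-generation means mu.

    ``G`` is the mean year-corrected flowering time of the progenitor's
    recorded plants; ``mu`` is the mean of G over progenitors of the same
    generation; ``G_centered = G - mu`` is the regression response.
    Progenitors without phenotype records are simply absent from the output.
    """
    means = (corrected.dropna(subset=["Y"])
             .groupby("progenitor_id")["Y"].mean())
    rows = []
    for p in pedigree.topological_order():
        if p.id in means.index:
            rows.append({"progenitor_id": p.id, "generation": p.generation,
                         "population": p.population, "family": p.family,
                         "G": float(means[p.id])})
    df = pd.DataFrame(rows, columns=["progenitor_id", "generation",
                                     "population", "family", "G"])
    mu = df.groupby("generation")["G"].transform("mean")
    df["mu"] = mu
    df["G_centered"] = df["G"] - mu
    return df


def _fit_xy(g: np.ndarray, x: np.ndarray, y: np.ndarray
            ) -> tuple[float, float, float]:
    """Least-squares (a, d) for g ~ a*x + d*y (no intercept) and the R2.

    Uses the pseudo-inverse so that a design without heterozygotes (y all
    zero) yields d = 0 rather than an error.
    """
    X = np.column_stack([x, y])
    xtx = X.T @ X
    coef = np.linalg.pinv(xtx) @ X.T @ g
    resid = g - X @ coef
    sst = float((g ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / sst if sst > 0 else 0.0
    return float(coef[0]), float(coef[1]), r2


def fit_additive_dominance(bv: pd.DataFrame,
                           genotypes: Mapping[str, str],
                           ) -> tuple[float, float, float]:
    """Estimate (a, d, R2) for one marker from observed genotypes.

    ``bv`` is a (possibly scope-restricted) breeding-value frame from
    :func:`breeding_values`; ``genotypes`` maps progenitor id to a label.
    Progenitors with missing genotype are dropped.  Raises if the marker
    does not segregate within the scope.
    """
    enc = [encode_genotype(genotypes.get(pid))
           for pid in bv["progenitor_id"]]
    x = np.array([e[0] for e in enc])
    y = np.array([e[1] for e in enc])
    keep = ~np.isnan(x)
    x, y = x[keep], y[keep]
    g = bv["G_centered"].to_numpy(dtype=float)[keep]
    if len(np.unique(x + 2 * y)) < 2:
        raise ValueError("no segregation in scope")
    return _fit_xy(g, x, y)


def gene_drop(pedigree: Pedigree, n_sims: int, seed: int,
              founder_genotype: str = "Bb") -> pd.DataFrame:
    """Drop two alleles through the pedigree ``n_sims`` times.

    Founders start heterozygous (configurable for testing); every child's
    genotype is drawn from its parent's by the selfing transmission model.
    Returns a frame of genotype codes (0/1/2) with one row per simulation
    and one column per progenitor id.
    """
    rng = np.random.default_rng(seed)
    order = pedigree.topological_order()
    codes = {pid: np.empty(n_sims, dtype=np.int8) for pid in
             (p.id for p in order)}
    start = GENOTYPE_CODES[founder_genotype]
    for p in order:
        if p.parent_id is None:
            codes[p.id][:] = start
        else:
            parent = codes[p.parent_id]
            child = parent.copy()
            het = parent == 1
            if het.any():
                child[het] = rng.binomial(2, 0.5, size=int(het.sum()))
            codes[p.id] = child
    return pd.DataFrame(codes)


@dataclass
class AssociationResult:
    marker: str
    scope: str
    a: float
    d: float
    r2: float
    p_a: float
    p_d: float
    n_sims: int
    n_effective_sims: int


def _scope_ids(bv: pd.DataFrame, scope: str) -> pd.DataFrame:
    if scope == "global":
        sub = bv[bv["population"].isin(("Early", "Late"))]
    elif scope == "within_Early":
        sub = bv[bv["population"] == "Early"]
    elif scope == "within_Late":
        sub = bv[bv["population"] == "Late"]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    # re-center within scope so mu_i is the scope's per-generation mean
    sub = sub.copy()
    sub["G_centered"] = sub["G"] - sub.groupby("generation")["G"].transform(
        "mean")
    return sub


def association_pvalue(pedigree: Pedigree, bv: pd.DataFrame,
                       genotypes: Mapping[str, str], marker: str,
                       n_sims: int, seed: int, scope: str = "global",
                       drops: Optional[pd.DataFrame] = None,
                       ) -> AssociationResult:
    """Gene-dropping empirical P-values for one marker in one scope.

    The observed (a, d) are refitted against ``n_sims`` dropped genotype
    matrices on the *same* breeding values;
    ``p = (1 + #{|effect_sim| >= |effect_obs|}) / (n_eff + 1)``.
    Simulations in which the marker does not segregate within the scope
    cannot be refitted and are excluded from the denominator
    (``n_effective_sims`` reports what remains).
    """
    sub = _scope_ids(bv, scope)
    a_obs, d_obs, r2 = fit_additive_dominance(sub, genotypes)
    if drops is None:
        drops = gene_drop(pedigree, n_sims, seed)
    ids = list(sub["progenitor_id"])
    g = sub["G_centered"].to_numpy(dtype=float)
    # restrict to progenitors with an observed genotype, as in the real fit
    observed = np.array([genotypes.get(pid) is not None
                         and not (isinstance(genotypes.get(pid), float)
                                  and np.isnan(genotypes.get(pid)))
                         for pid in ids])
    g = g[observed]
    codes = drops[[pid for pid, ok in zip(ids, observed) if ok]].to_numpy()
    x = codes.astype(float) - 1.0           # (n_sims, n)
    y = (codes == 1).astype(float)
    seg = codes.max(axis=1) != codes.min(axis=1)
    a_sim, d_sim = _batch_fit(g, x[seg], y[seg])
    n_eff = int(seg.sum())
    p_a = (1.0 + np.count_nonzero(np.abs(a_sim) >= abs(a_obs))) / (n_eff + 1.0)
    p_d = (1.0 + np.count_nonzero(np.abs(d_sim) >= abs(d_obs))) / (n_eff + 1.0)
    return AssociationResult(marker=marker, scope=scope, a=a_obs, d=d_obs,
                             r2=r2, p_a=p_a, p_d=p_d, n_sims=len(drops),
                             n_effective_sims=n_eff)


def _batch_fit(g: np.ndarray, x: np.ndarray, y: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (a, d) least squares across simulations."""
    if len(x) == 0:
        return np.empty(0), np.empty(0)
    sxx = (x * x).sum(axis=1)
    sxy = (x * y).sum(axis=1)
    syy = (y * y).sum(axis=1)
    sxg = x @ g
    syg = y @ g
    xtx = np.stack([np.stack([sxx, sxy], axis=-1),
                    np.stack([sxy, syy], axis=-1)], axis=-2)
    rhs = np.stack([sxg, syg], axis=-1)
    coef = np.einsum("nij,nj->ni", np.linalg.pinv(xtx), rhs)
    return coef[:, 0], coef[:, 1]


def association_scan(pedigree: Pedigree, bv: pd.DataFrame,
                     genotypes: pd.DataFrame, n_sims: int, seed: int,
                     scopes: Sequence[str] = SCOPES) -> pd.DataFrame:
    """Run the gene-dropping association test for every marker and scope.

    ``genotypes`` is the long-form inferred genotype table
    (progenitor_id, marker, genotype).  One shared set of gene drops is
    reused across markers (the null genotype flow does not depend on the
    marker).  Markers that do not segregate in a scope are skipped there.
    """
    drops = gene_drop(pedigree, n_sims, seed)
    rows = []
    for marker, sub in genotypes.groupby("marker", sort=True):
        geno = dict(zip(sub["progenitor_id"], sub["genotype"]))
        for scope in scopes:
            try:
                res = association_pvalue(pedigree, bv, geno, str(marker),
                                         n_sims, seed, scope, drops=drops)
            except ValueError:
                continue
            rows.append(vars(res))
    return pd.DataFrame(rows, columns=["marker", "scope", "a", "d", "r2",
                                       "p_a", "p_d", "n_sims",
                                       "n_effective_sims"])
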