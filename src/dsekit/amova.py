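"""Hierarchical analysis of molecular variance (AMOVA) on band frequencies.

Progenitor band-frequency profiles (one 0/0.5/1 value per marker) are
treated as points in Euclidean marker space.  Total sum of squares is
partitioned along the two-level hierarchy population > family > progenitor:

    SS_total = SS_among_populations + SS_among_families_within
               + SS_within_families                      (exact identity)

Variance components are obtained from the nested random-effects expected
mean squares with the standard unequal-sample-size coefficients; reported
percentages are each component over their sum.  Significance is assessed by
permutation: the among-population component by permuting progenitors across
the whole table (against the fixed label structure), the among-family
component by permuting progenitors within populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import Pedigree

COMPONENTS = ("among_populations", "among_families", "within_families")


@dataclass
class AmovaResult:
    ss: dict[str, float]              # sums of squares incl. "total"
    df: dict[str, int]
    sigma2: dict[str, float]          # variance components
    percentages: dict[str, float]
    p_values: dict[str, float]
    n_permutations: int
    n_imputed: int                    # missing frequencies mean-imputed

    def as_frame(self) -> pd.DataFrame:
        rows = [{"component": c, "df": self.df[c], "SS": self.ss[c],
                 "sigma2": self.sigma2[c],
                 "percent": self.percentages[c],
                 "p_value": self.p_values.get(c, float("nan"))}
                for c in COMPONENTS]
        return pd.DataFrame(rows)


def _sums_of_squares(z: np.ndarray, pop: np.ndarray, fam: np.ndarray
                     ) -> tuple[float, float, float, float]:
    grand = z.mean(axis=0)
    ss_total = float(((z - grand) ** 2).sum())
    ss_pop = 0.0
    ss_fam = 0.0
    ss_within = 0.0
    for p in np.unique(pop):
        zp = z[pop == p]
        cp = zp.mean(axis=0)
        ss_pop += len(zp) * float(((cp - grand) ** 2).sum())
        for f in np.unique(fam[pop == p]):
            zf = z[(pop == p) & (fam == f)]
            cf = zf.mean(axis=0)
            ss_fam += len(zf) * float(((cf - cp) ** 2).sum())
            ss_within += float(((zf - cf) ** 2).sum())
    return ss_total, ss_pop, ss_fam, ss_within


def _components(z: np.ndarray, pop: np.ndarray, fam: np.ndarray
                ) -> tuple[dict, dict, dict]:
    ss_total, ss_pop, ss_fam, ss_within = _sums_of_squares(z, pop, fam)
    n = len(z)
    pops = np.unique(pop)
    n_p = len(pops)
    n_f = len({(p_, f_) for p_, f_ in zip(pop, fam)})
    df = {"among_populations": n_p - 1, "among_families": n_f - n_p,
          "within_families": n - n_f, "total": n - 1}

    fam_sizes: dict[str, list[int]] = {}
    pop_sizes: dict[str, int] = {}
    for p in pops:
        mask = pop == p
        pop_sizes[p] = int(mask.sum())
        fam_sizes[p] = [int(((fam == f) & mask).sum())
                        for f in np.unique(fam[mask])]
    a = sum(sum(s ** 2 for s in fam_sizes[p]) / pop_sizes[p] for p in pops)
    b = sum(sum(s ** 2 for s in fam_sizes[p]) for p in pops) / n
    c = sum(v ** 2 for v in pop_sizes.values()) / n
    n1 = (n - a) / df["among_families"] if df["among_families"] > 0 else 1.0
    n2 = (a - b) / df["among_populations"]
    n3 = (n - c) / df["among_populations"]

    ms_within = ss_within / df["within_families"] \
        if df["within_families"] > 0 else 0.0
    ms_fam = ss_fam / df["among_families"] if df["among_families"] > 0 else 0.0
    ms_pop = ss_pop / df["among_populations"]
    sigma_c = ms_within
    sigma_b = (ms_fam - sigma_c) / n1 if df["among_families"] > 0 else 0.0
    sigma_a = (ms_pop - sigma_c - n2 * sigma_b) / n3
    sigma2 = {"among_populations": sigma_a, "among_families": sigma_b,
              "within_families": sigma_c}
    ss = {"among_populations": ss_pop, "among_families": ss_fam,
          "within_families": ss_within, "total": ss_total}
    return ss, df, sigma2


def amova(freq: pd.DataFrame, pedigree: Pedigree, n_perms: int = 1000,
          seed: int = 0) -> AmovaResult:
    """Nested AMOVA of band-frequency profiles over populations and families.

    ``freq`` is the progenitor x marker band-frequency matrix (e.g. from
    :func:`dsekit.ldmap.band_frequency_matrix`).  Only Early/Late
    progenitors enter the analysis (the control is not part of the
    selection hierarchy).  Missing frequencies are mean-imputed per marker;
    the count of imputed cells is reported.  Families reduced to a single
    progenitor still contribute to the among-family level through the
    unequal-size coefficients.
    """
    ids = [pid for pid in freq.index
           if pid in pedigree and pedigree[pid].population in ("Early", "Late")]
    if not ids:
        raise ValueError("no Early/Late progenitors in frequency matrix")
    sub = freq.loc[ids]
    pop = np.array([pedigree[i].population for i in ids])
    fam = np.array([pedigree[i].family for i in ids])
    if len(np.unique(pop)) < 2:
        raise ValueError("need at least two populations")
    if len(np.unique(fam)) < 2:
        raise ValueError("need at least two families")

    n_imputed = int(sub.isna().to_numpy().sum())
    z = sub.to_numpy(dtype=float)
    if n_imputed:
        col_means = np.nanmean(z, axis=0)
        col_means = np.where(np.isnan(col_means), 0.0, col_means)
        z = np.where(np.isnan(z), col_means[None, :], z)

    ss, df, sigma2 = _components(z, pop, fam)
    total_var = sum(sigma2.values())
    percentages = {k: (100.0 * v / total_var if total_var != 0 else 0.0)
                   for k, v in sigma2.items()}

    rng = np.random.default_rng(seed)
    exceed = {"among_populations": 0, "among_families": 0}
    for _ in range(n_perms):
        perm = rng.permutation(len(z))
        _, _, s_glob = _components(z[perm], pop, fam)
        if s_glob["among_populations"] >= sigma2["among_populations"] - 1e-12:
            exceed["among_populations"] += 1
        within = np.arange(len(z))
        for p in np.unique(pop):
            mask = np.flatnonzero(pop == p)
            within[mask] = rng.permutation(mask)
        _, _, s_fam = _components(z[within], pop, fam)
        if s_fam["among_families"] >= sigma2["among_families"] - 1e-12:
            exceed["among_families"] += 1
    p_values = {k: (1.0 + v) / (n_perms + 1.0) for k, v in exceed.items()}

    return AmovaResult(ss=ss, df=df, sigma2=sigma2, percentages=percentages,
                       p_values=p_values, n_permutations=n_perms,
                       n_imputed=n_imputed)
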