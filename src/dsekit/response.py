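"""Thermal time, year correction, selection response and heritability.

Flowering dates are analyzed on the thermal-time scale (degree-days above a
base temperature Tb, capped at an optimum To).  Because each generation of
the experiment is grown in a different year, raw flowering times confound
the response to selection with seasonal effects; the correction model

    Z_ijklm = Year_i + b_j * gener_i + e_ijklm

(one fixed effect per year, one linear generation trend per selected
population, the unselected control line pinned to slope zero) identifies
the year effects, which are then subtracted: Y = Z - Year_hat.  The
response of each family is the slope of Y on generation; the within-family
broad-sense heritability at a given generation is the between-progenitor
variance fraction from a one-way random-effects model on Y.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .pedigree import Pedigree


@dataclass(frozen=True)
class ThermalTimeParams:
    """Degree-day parameters: base temperature and optimum cap (deg C)."""

    Tb: float = 6.0
    To: float = 30.0

    def __post_init__(self) -> None:
        if self.To <= self.Tb:
            raise ValueError("To must exceed Tb")


def thermal_time(daily_mean_temps: Sequence[float],
                 params: ThermalTimeParams = ThermalTimeParams()) -> float:
    """Accumulated thermal time of a run of days (capped linear model).

    Each day contributes ``max(0, min(T, To) - Tb)`` degree-days.
    """
    t = np.asarray(daily_mean_temps, dtype=float)
    if t.size == 0:
        raise ValueError("empty temperature series")
    return float(np.clip(np.minimum(t, params.To) - params.Tb, 0.0,
                         None).sum())


@dataclass
class ResponseFit:
    """Per-family linear response to selection (slope of Y on generation)."""

    family: str
    slope: float            # degree-days per generation
    intercept: float
    stde: float
    p_value: float
    adj_r2: float
    df: int                 # residual degrees of freedom
    resid_sd: float


@dataclass
class HeritabilityRecord:
    family: str
    generation: int
    var_g: float
    var_e: float

    @property
    def h2(self) -> float:
        tot = self.var_g + self.var_e
        return self.var_g / tot if tot > 0 else 0.0


def _attach_generation(phenotypes: pd.DataFrame, pedigree: Pedigree
                       ) -> pd.DataFrame:
    df = phenotypes.copy()
    df["generation"] = [pedigree[pid].generation
                        for pid in df["progenitor_id"]]
    df["population"] = [pedigree[pid].population
                       for pid in df["progenitor_id"]]
    df["family"] = [pedigree[pid].family for pid in df["progenitor_id"]]
    return df


def fit_year_correction(phenotypes: pd.DataFrame, pedigree: Pedigree
                        ) -> tuple[dict[int, float], pd.DataFrame]:
    """Estimate fixed year effects and return year-corrected phenotypes.

    Fits ``Z = Year_i + b_pop * generation`` by least squares with the
    Control population constrained to zero slope (the control line is what
    anchors the year scale when year and generation advance together).
    Returns ``(year_effects, corrected)`` where ``corrected`` carries a new
    column ``Y = flowering_tt - Year_hat``.
    """
    df = _attach_generation(phenotypes, pedigree).dropna(
        subset=["flowering_tt"])
    years = sorted(df["year"].unique())
    pops = [p for p in ("Early", "Late") if (df["population"] == p).any()]
    has_control = (df["population"] == "Control").any()

    if not has_control and df.groupby("year")["generation"].nunique().max() == 1 \
            and len(years) > 1:
        warnings.warn("year-generation confounding; identification relies "
                      "on control", UserWarning, stacklevel=2)

    n = len(df)
    X = np.zeros((n, len(years) + len(pops)))
    for i, yr in enumerate(years):
        X[:, i] = (df["year"] == yr).to_numpy(dtype=float)
    for j, pop in enumerate(pops):
        X[:, len(years) + j] = np.where(df["population"] == pop,
                                        df["generation"], 0.0)
    z = df["flowering_tt"].to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(X, z, rcond=None)
    year_effects = {int(yr): float(coef[i]) for i, yr in enumerate(years)}

    corrected = _attach_generation(phenotypes, pedigree)
    corrected["Y"] = corrected["flowering_tt"] - corrected["year"].map(
        year_effects)
    return year_effects, corrected


def fit_family_response(corrected: pd.DataFrame, family: str,
                        generation_range: Optional[tuple[int, int]] = None,
                        ) -> ResponseFit:
    """OLS slope of corrected flowering time on generation within a family.

    ``generation_range`` is inclusive (e.g. ``(0, 6)`` or ``(7, 16)``,
    matching the two analysis windows of the experiment).
    """
    sub = corrected[corrected["family"] == family].dropna(subset=["Y"])
    if generation_range is not None:
        lo, hi = generation_range
        sub = sub[(sub["generation"] >= lo) & (sub["generation"] <= hi)]
    if sub["generation"].nunique() < 3:
        raise ValueError(
            f"insufficient generations for family {family!r}: need >= 3 "
            f"distinct, got {sub['generation'].nunique()}")
    X = sm.add_constant(sub["generation"].to_numpy(dtype=float))
    fit = sm.OLS(sub["Y"].to_numpy(dtype=float), X).fit()
    resid_sd = float(np.sqrt(fit.ssr / fit.df_resid)) if fit.df_resid > 0 \
        else float("nan")
    return ResponseFit(
        family=family, slope=float(fit.params[1]),
        intercept=float(fit.params[0]), stde=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]), adj_r2=float(fit.rsquared_adj),
        df=int(fit.df_resid), resid_sd=resid_sd)


def estimate_H2(corrected: pd.DataFrame, family: str, generation: int,
                reml: bool = True) -> HeritabilityRecord:
    """Broad-sense heritability within a family at one generation.

    One-way random-effects decomposition of corrected flowering time with
    progenitor as the random factor: H2 = varG / (varG + varE), varG being
    the between-progenitor variance.  Negative component estimates are
    truncated to zero, so H2 always lies in [0, 1].  REML via a linear
    mixed model, with the ANOVA method-of-moments estimator as fallback for
    degenerate fits (the two coincide for balanced designs).
    """
    sub = corrected[(corrected["family"] == family)
                    & (corrected["generation"] == generation)].dropna(
                        subset=["Y"])
    groups = sub.groupby("progenitor_id")["Y"]
    if groups.ngroups < 2:
        raise ValueError(f"H2 undefined: single progenitor in family "
                         f"{family!r} at generation {generation}")
    var_g = var_e = None
    if reml:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = sm.MixedLM(sub["Y"].to_numpy(dtype=float),
                                np.ones((len(sub), 1)),
                                groups=sub["progenitor_id"].to_numpy())
                res = md.fit(reml=True, method="lbfgs")
            var_g = float(res.cov_re.iloc[0, 0])
            var_e = float(res.scale)
            if not (np.isfinite(var_g) and np.isfinite(var_e)):
                var_g = None
        except Exception:
            var_g = None
    if var_g is None:
        var_g, var_e = _anova_components(groups)
    return HeritabilityRecord(family=family, generation=generation,
                              var_g=max(var_g, 0.0), var_e=max(var_e, 0.0))


def _anova_components(groups) -> tuple[float, float]:
    """One-way ANOVA method-of-moments variance components."""
    sizes = groups.size().to_numpy(dtype=float)
    means = groups.mean().to_numpy(dtype=float)
    n_tot = sizes.sum()
    k = len(sizes)
    grand = (sizes * means).sum() / n_tot
    ss_between = float((sizes * (means - grand) ** 2).sum())
    ss_within = float(groups.apply(lambda y: ((y - y.mean()) ** 2).sum()).sum())
    df_within = n_tot - k
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    n0 = (n_tot - (sizes ** 2).sum() / n_tot) / (k - 1)
    ms_between = ss_between / (k - 1)
    var_e = ms_within
    var_g = max((ms_between - ms_within) / n0, 0.0)
    return var_g, var_e


def family_H2_summary(corrected: pd.DataFrame, family: str,
                      generations: Iterable[int]) -> tuple[float, float]:
    """Median and maximum H2 of a family over a set of generations.

    Generations where H2 is undefined (a single progenitor) are skipped.
    """
    values = []
    for g in generations:
        try:
            values.append(estimate_H2(corrected, family, g).h2)
        except ValueError:
            continue
    if not values:
        return float("nan"), float("nan")
    return float(np.median(values)), float(max(values))


def standardize_response(family_means: pd.Series, control_resid_sd: float
                         ) -> pd.Series:
    """Control-standardized response series for cross-experiment comparison.

    ``family_means`` is the per-generation mean corrected flowering time of
    one family (index = generation).  The series is centered on its first
    generation and scaled by the residual standard deviation of the control
    line's regression.
    """
    if not control_resid_sd > 0:
        raise ValueError("control residual sd must be positive")
    s = family_means.sort_index()
    return (s - s.iloc[0]) / control_resid_sd


def response_table(corrected: pd.DataFrame,
                   generation_range: tuple[int, int],
                   families: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per-family response and heritability summary over one window.

    Columns: Family, df, Response, stde, p_value, R2, MedianH2, MaxH2.
    """
    if families is None:
        families = sorted(corrected["family"].unique())
    lo, hi = generation_range
    rows = []
    for fam in families:
        try:
            fit = fit_family_response(corrected, fam, generation_range)
        except ValueError:
            continue
        med, mx = family_H2_summary(corrected, fam, range(lo, hi + 1))
        rows.append({"Family": fam, "df": fit.df, "Response": fit.slope,
                     "stde": fit.stde, "p_value": fit.p_value,
                     "R2": fit.adj_r2, "MedianH2": med, "MaxH2": mx})
    return pd.DataFrame(rows, columns=["Family", "df", "Response", "stde",
                                       "p_value", "R2", "MedianH2", "MaxH2"])
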