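"""Thermal time, year correction, response slopes and heritability."""

import numpy as np
import pandas as pd
import pytest

from dsekit.pedigree import Pedigree, Progenitor
from dsekit.response import (HeritabilityRecord, ThermalTimeParams,
                             estimate_H2, family_H2_summary,
                             fit_family_response, fit_year_correction,
                             response_table, standardize_response,
                             thermal_time)


def make_pedigree(n_generations: int, families=("FE1",), population="Early",
                  with_control=False) -> Pedigree:
    progenitors = []
    for fam in families:
        for g in range(n_generations + 1):
            parent = None if g == 0 else f"{fam}_G{g-1}"
            progenitors.append(Progenitor(f"{fam}_G{g}", parent, g, fam,
                                          population, "F252"))
    if with_control:
        for g in range(n_generations + 1):
            parent = None if g == 0 else f"CTRL_G{g-1}"
            progenitors.append(Progenitor(f"CTRL_G{g}", parent, g,
                                          "F-CONTROL", "Control", "F252"))
    return Pedigree(progenitors)


def phenotype_rows(pid, generation, year, values):
    return [{"progenitor_id": pid, "plant_index": i + 1, "year": year,
             "block": "row1", "flowering_raw": np.nan, "flowering_tt": v}
            for i, v in enumerate(values)]


class TestThermalTime:
    def test_constant_mild_days(self):
        assert thermal_time([16.0] * 10) == pytest.approx(100.0)

    def test_cold_days_contribute_nothing(self):
        assert thermal_time([5.0, 2.0, -3.0]) == 0.0

    def test_hot_days_capped_at_optimum(self):
        # 5 days at 35 C with To=30 accumulate 24 degree-days each
        assert thermal_time([35.0] * 5) == pytest.approx(120.0)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            thermal_time([])

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ThermalTimeParams(Tb=10.0, To=9.0)


class TestYearCorrection:
    def test_single_year_control_only(self):
        ped = make_pedigree(0, families=(), with_control=True)
        rows = phenotype_rows("CTRL_G0", 0, 2005, [100.0, 110.0, 120.0])
        effects, corrected = fit_year_correction(pd.DataFrame(rows), ped)
        assert effects[2005] == pytest.approx(110.0)
        assert corrected["Y"].mean() == pytest.approx(0.0)

    def test_known_year_effects_recovered(self):
        """Year effects {+30, -10} around a known slope are recovered when a
        flat control line anchors the year scale."""
        rng = np.random.default_rng(42)
        ped = make_pedigree(1, families=("FL1",), population="Late",
                            with_control=True)
        rows = []
        true_year = {2019: 1030.0, 2020: 990.0}
        slope = 12.0
        for g, year in enumerate(true_year):
            rows += phenotype_rows(f"FL1_G{g}", g, year,
                                   true_year[year] + slope * g
                                   + rng.normal(0, 5, 30))
            rows += phenotype_rows(f"CTRL_G{g}", g, year,
                                   true_year[year] + rng.normal(0, 5, 30))
        effects, _ = fit_year_correction(pd.DataFrame(rows), ped)
        # difference of year effects is what is identified
        got = effects[2019] - effects[2020]
        assert got == pytest.approx(40.0, abs=2 * 5 / np.sqrt(30) * 2)

    def test_confounded_design_without_control_warns(self):
        ped = make_pedigree(2)
        rows = []
        for g in range(3):
            rows += phenotype_rows(f"FE1_G{g}", g, 2000 + g,
                                   [1000.0 + g, 1001.0 + g])
        with pytest.warns(UserWarning, match="confounding"):
            fit_year_correction(pd.DataFrame(rows), ped)

    def test_correction_idempotent(self):
        rng = np.random.default_rng(7)
        ped = make_pedigree(3, with_control=True)
        rows = []
        for g in range(4):
            rows += phenotype_rows(f"FE1_G{g}", g, 2000 + g,
                                   1000.0 + 10 * g + rng.normal(0, 3, 12))
            rows += phenotype_rows(f"CTRL_G{g}", g, 2000 + g,
                                   1000.0 + rng.normal(0, 3, 12))
        _, corrected = fit_year_correction(pd.DataFrame(rows), ped)
        again = corrected.drop(columns=["Y", "generation", "population",
                                        "family"]).assign(
            flowering_tt=corrected["Y"])
        effects2, _ = fit_year_correction(again, ped)
        assert max(abs(v) for v in effects2.values()) < 1e-6


class TestFamilyResponse:
    def _corrected(self, slope, noise_sd, n_gens, seed=0, family="FE1"):
        rng = np.random.default_rng(seed)
        ped = make_pedigree(n_gens, families=(family,))
        rows = []
        for g in range(n_gens + 1):
            rows += phenotype_rows(f"{family}_G{g}", g, 2000 + g,
                                   slope * g + rng.normal(0, noise_sd, 12))
        df = pd.DataFrame(rows)
        df["generation"] = [ped[p].generation for p in df["progenitor_id"]]
        df["family"] = family
        df["Y"] = df["flowering_tt"]
        return df

    def test_noiseless_slope_exact(self):
        fit = fit_family_response(self._corrected(5.0, 0.0, 4), "FE1")
        assert fit.slope == pytest.approx(5.0)
        assert fit.adj_r2 == pytest.approx(1.0)

    def test_seeded_recovery_within_two_stde(self):
        fit = fit_family_response(self._corrected(12.0, 30.0, 6, seed=3),
                                  "FE1")
        assert abs(fit.slope - 12.0) < 2 * fit.stde

    def test_generation_window_restricts_fit(self):
        df = self._corrected(5.0, 0.0, 8)
        df.loc[df["generation"] > 4, "Y"] = 0.0  # plateau after G4
        fit = fit_family_response(df, "FE1", (0, 4))
        assert fit.slope == pytest.approx(5.0)

    def test_null_slopes_rarely_significant(self):
        hits = 0
        n = 60
        for seed in range(n):
            fit = fit_family_response(self._corrected(0.0, 20.0, 4,
                                                      seed=seed), "FE1")
            hits += fit.p_value < 0.05
        assert hits / n <= 0.10

    def test_too_few_generations_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            fit_family_response(self._corrected(1.0, 1.0, 1), "FE1")


class TestHeritability:
    def _family_gen(self, progenitor_means, noise_sd, n_plants=12, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i, mu in enumerate(progenitor_means):
            for m in range(n_plants):
                rows.append({"progenitor_id": f"P{i}", "family": "FE1",
                             "generation": 3,
                             "Y": mu + rng.normal(0, noise_sd)})
        return pd.DataFrame(rows)

    def test_no_progenitor_differences_gives_zero(self):
        df = self._family_gen([100.0] * 5, noise_sd=10.0, seed=1)
        rec = estimate_H2(df, "FE1", 3)
        assert rec.h2 < 0.15  # sampling noise only; truncated at 0

    def test_no_residual_variance_gives_one(self):
        df = self._family_gen([100.0, 120.0, 140.0], noise_sd=0.0)
        rec = estimate_H2(df, "FE1", 3)
        assert rec.h2 == pytest.approx(1.0)

    def test_h2_bounded(self):
        rec = HeritabilityRecord("FE1", 1, var_g=5.0, var_e=15.0)
        assert rec.h2 == pytest.approx(0.25)

    def test_seeded_recovery_of_h2(self):
        """varG=100, varE=300 (H2=0.25): mean estimate over seeded
        replicates lands within 0.05."""
        rng = np.random.default_rng(11)
        estimates = []
        for _ in range(120):
            means = rng.normal(0, 10.0, 10)
            df = self._family_gen(means, noise_sd=np.sqrt(300.0),
                                  seed=int(rng.integers(2 ** 31)))
            estimates.append(estimate_H2(df, "FE1", 3).h2)
        assert abs(np.mean(estimates) - 0.25) < 0.05

    def test_reml_and_moments_agree_on_balanced_data(self):
        df = self._family_gen([90.0, 110.0, 130.0, 100.0], noise_sd=15.0,
                              seed=5)
        a = estimate_H2(df, "FE1", 3, reml=True)
        b = estimate_H2(df, "FE1", 3, reml=False)
        assert a.h2 == pytest.approx(b.h2, abs=0.02)

    def test_single_progenitor_rejected(self):
        df = self._family_gen([100.0], noise_sd=1.0)
        with pytest.raises(ValueError, match="undefined"):
            estimate_H2(df, "FE1", 3)

    def test_null_distribution_piles_at_zero(self):
        # with varG=0 the truncated estimator should often return exactly 0
        zeros = 0
        for seed in range(40):
            df = self._family_gen([50.0] * 6, noise_sd=20.0, seed=seed)
            zeros += estimate_H2(df, "FE1", 3).h2 < 1e-6
        assert zeros / 40 > 0.3


class TestStandardization:
    def test_flat_series_is_zero(self):
        s = pd.Series({0: 100.0, 1: 100.0, 2: 100.0})
        assert (standardize_response(s, 10.0) == 0.0).all()

    def test_scaling(self):
        s = pd.Series({1: 100.0, 2: 150.0})
        out = standardize_response(s, 10.0)
        assert out.loc[2] == pytest.approx(5.0)

    def test_zero_control_sd_rejected(self):
        with pytest.raises(ValueError):
            standardize_response(pd.Series({0: 1.0}), 0.0)


class TestResponseTable:
    def test_columns_and_content(self):
        rng = np.random.default_rng(2)
        ped = make_pedigree(4, families=("FE1", "FL1"))
        rows = []
        for fam, slope in (("FE1", -8.0), ("FL1", 10.0)):
            for g in range(5):
                rows += phenotype_rows(
                    f"{fam}_G{g}", g, 2000 + g,
                    1000 + slope * g + rng.normal(0, 10, 12))
        df = pd.DataFrame(rows)
        df["generation"] = [ped[p].generation for p in df["progenitor_id"]]
        df["family"] = [ped[p].family for p in df["progenitor_id"]]
        df["Y"] = df["flowering_tt"]
        table = response_table(df, (0, 4))
        assert list(table.columns) == ["Family", "df", "Response", "stde",
                                       "p_value", "R2", "MedianH2", "MaxH2"]
        fe1 = table.set_index("Family").loc["FE1"]
        fl1 = table.set_index("Family").loc["FL1"]
        assert fe1["Response"] < 0 < fl1["Response"]
        assert fe1["p_value"] < 0.001
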