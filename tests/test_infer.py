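"""Genotype inference: DP exactness, Mendelian filters, trajectories."""

import math

import numpy as np
import pandas as pd
import pytest

from dsekit.infer import (UninformativeLocusError, band_observation_loglik,
                          estimate_heterozygote_trajectory,
                          filter_non_mendelian, infer_genotypes,
                          infer_locus_genotypes)
from dsekit.markers import MarkerEffect, ObservationModel
from dsekit.pedigree import Pedigree, Progenitor
from dsekit.simulate import SimConfig, simulate_dse

from conftest import (brute_force_locus_loglik, chain_pedigree,
                      random_pedigree)

ERROR_FREE = ObservationModel(fp=0.0, fn=0.0)


class TestObservationLoglik:
    def test_impossible_observation_is_minus_inf(self):
        assert band_observation_loglik(0, 1.0, ERROR_FREE) == -math.inf

    def test_certain_observation_is_zero(self):
        assert band_observation_loglik(2, 1.0, ERROR_FREE) == 0.0

    def test_missing_contributes_log_one(self):
        assert band_observation_loglik(1, float("nan"), ERROR_FREE) == 0.0
        assert band_observation_loglik(1, None, ERROR_FREE) == 0.0

    def test_heterozygote_absent_matches_enumeration(self):
        # P(no band in bulk | Bb) = (3/8)^3 with three independent S1
        got = band_observation_loglik(1, 0.0, ERROR_FREE)
        assert got == pytest.approx(math.log(27 / 512), abs=1e-12)


class TestLocusInference:
    def test_all_present_gives_all_BB(self):
        ped = chain_pedigree(3)
        band = {pid: 1.0 for pid in ped.ids}
        inf = infer_locus_genotypes(ped, band, ObservationModel())
        assert all(g == 2 for g in inf.genotypes.values())

    def test_identifiable_fixture_recovered_exactly(self):
        """On a pedigree where every genotype is pinned down by segregation
        (each true BB has two band-present offspring, each Bb has a
        band-absent descendant), error-free bands give exact recovery."""
        rows = [
            ("F", None, 0), ("C1", "F", 1), ("C2", "F", 1), ("C3", "F", 1),
            ("C1a", "C1", 2), ("C1b", "C1", 2),
            ("D1", "C3", 2), ("D2", "C3", 2),
            ("E1", "D2", 3), ("E2", "D2", 3), ("E3", "D2", 3),
        ]
        ped = Pedigree(Progenitor(i, p, g, "FL1", "Late", "F252")
                       for i, p, g in rows)
        truth = {"F": 1, "C1": 2, "C2": 0, "C3": 1, "C1a": 2, "C1b": 2,
                 "D1": 0, "D2": 2, "E1": 2, "E2": 2, "E3": 2}
        band = {pid: (1.0 if g > 0 else 0.0) for pid, g in truth.items()}
        inf = infer_locus_genotypes(ped, band, ERROR_FREE)
        assert inf.genotypes == truth

    def test_uninformative_locus_raises(self):
        ped = chain_pedigree(2)
        with pytest.raises(UninformativeLocusError):
            infer_locus_genotypes(ped, {}, ObservationModel())

    def test_mendelian_consistency_when_error_free(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            ped = random_pedigree(rng, 7)
            # bands simulated from a genuine gene drop so a consistent
            # assignment exists
            from dsekit.genedrop import gene_drop
            codes = gene_drop(ped, 1, int(rng.integers(2 ** 30))).iloc[0]
            band = {pid: (1.0 if codes[pid] == 2 else
                          0.0 if codes[pid] == 0 else
                          float(rng.random() < 485 / 512))
                    for pid in ped.ids}
            inf = infer_locus_genotypes(ped, band, ERROR_FREE)
            for p in ped:
                if p.parent_id is not None:
                    gp, gc = inf.genotypes[p.parent_id], inf.genotypes[p.id]
                    assert not (gp in (0, 2) and gc != gp)

    def test_dp_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(123)
        model = ObservationModel(fp=0.05, fn=0.05)
        for _ in range(25):
            ped = random_pedigree(rng, int(rng.integers(3, 9)))
            band = {pid: float(rng.integers(0, 2)) for pid in ped.ids}
            inf = infer_locus_genotypes(ped, band, model)
            oracle = brute_force_locus_loglik(ped, band, model)
            assert inf.loglik == pytest.approx(oracle, abs=1e-9)

    def test_tie_break_is_deterministic(self):
        ped = chain_pedigree(2)
        band = {pid: float("nan") for pid in ped.ids}
        band[ped.ids[0]] = 1.0
        a = infer_locus_genotypes(ped, band, ObservationModel())
        b = infer_locus_genotypes(ped, band, ObservationModel())
        assert a.genotypes == b.genotypes

    def test_genotype_accuracy_with_scoring_errors(self):
        """Parameter recovery with 5% scoring errors.

        Dominant markers leave some heterozygotes unidentifiable (a Bb whose
        bulk and descendants all show the band is less likely than BB), so
        perfect recovery is impossible in principle; the calibrated bars
        are >= 88% of all entries and >= 97% of homozygous-truth entries,
        averaged over seeded replicates of the default design.
        """
        model = ObservationModel(fp=0.05, fn=0.05)
        acc, hom_acc = [], []
        for rep in range(12):
            cfg = SimConfig(n_generations=6, n_progenitors_kept=10,
                            seed=300 + rep)
            ped, tg, _, bands = simulate_dse(cfg, model)
            inferred = infer_genotypes(ped, bands, model)
            merged = inferred.merge(tg, on=["progenitor_id", "marker"],
                                    suffixes=("_hat", "_true"))
            hits = merged["genotype_hat"] == merged["genotype_true"]
            acc.append(hits.mean())
            hom = merged["genotype_true"] != "Bb"
            hom_acc.append(hits[hom].mean())
        assert np.mean(acc) >= 0.88
        assert np.mean(hom_acc) >= 0.97


class TestNonMendelianFilter:
    def _bands(self, states: dict[str, float], marker="M1") -> pd.DataFrame:
        return pd.DataFrame([
            {"progenitor_id": pid, "marker": marker, "system": "EcoRI_MseI",
             "state": s} for pid, s in states.items()])

    def test_mid_pedigree_singleton_discarded(self):
        ped = chain_pedigree(3)
        ids = ped.ids
        bands = self._bands({ids[0]: 0.0, ids[1]: 1.0, ids[2]: 0.0,
                             ids[3]: 0.0})
        retained, log = filter_non_mendelian(bands, ped)
        assert retained == []
        assert log[0]["action"] == "discarded"

    def test_transmitted_variant_retained(self):
        # band appears at G2 and is passed to G3 and G4: real polymorphism
        ped = chain_pedigree(4)
        ids = ped.ids
        bands = self._bands({ids[0]: 0.0, ids[1]: 0.0, ids[2]: 1.0,
                             ids[3]: 1.0, ids[4]: 1.0})
        retained, _ = filter_non_mendelian(bands, ped)
        assert retained == ["M1"]

    def test_founder_singleton_marker_discarded(self):
        # all polymorphism hinges on the founder's lone divergent state
        ped = chain_pedigree(3)
        ids = ped.ids
        bands = self._bands({ids[0]: 0.0, ids[1]: 1.0, ids[2]: 1.0,
                             ids[3]: 1.0})
        retained, log = filter_non_mendelian(bands, ped)
        assert retained == []
        assert log[0]["action"] == "discarded"

    def test_terminal_singleton_retained_but_flagged(self):
        ped = chain_pedigree(3)
        ids = ped.ids
        bands = self._bands({ids[0]: 0.0, ids[1]: 0.0, ids[2]: 0.0,
                             ids[3]: 1.0})
        retained, log = filter_non_mendelian(bands, ped)
        assert retained == ["M1"]
        assert "unconfirmed" in log[0]["reason"]

    def test_balanced_marker_untouched(self):
        ped = chain_pedigree(3)
        ids = ped.ids
        bands = self._bands({ids[0]: 1.0, ids[1]: 1.0, ids[2]: 0.0,
                             ids[3]: 0.0})
        retained, log = filter_non_mendelian(bands, ped)
        assert retained == ["M1"]
        assert log == []


class TestHeterozygoteTrajectory:
    def test_neutral_decay_rate_near_half(self):
        """Across seeded replicates of neutral lineages, the ratio of
        successive heterozygote frequencies (true genotypes) is about 1/2."""
        totals = np.zeros(4)
        counts = np.zeros(4)
        for rep in range(60):
            cfg = SimConfig(n_generations=3, n_progenitors_kept=3,
                            marker_loci=[MarkerEffect("M1", a=0.0),
                                         MarkerEffect("M2", a=0.0,
                                                      linkage_group="LG2")],
                            seed=900 + rep, include_control=False)
            ped, tg, _, _ = simulate_dse(cfg)
            traj = estimate_heterozygote_trajectory(tg, ped)
            for g, f in traj.items():
                totals[g] += f
                counts[g] += 1
        freq = totals / counts
        ratios = freq[1:] / freq[:-1]
        assert np.all(np.abs(ratios - 0.5) < 0.12)

    def test_all_homozygous_gives_zero(self):
        ped = chain_pedigree(2)
        geno = pd.DataFrame({
            "progenitor_id": ped.ids * 2,
            "marker": ["M1"] * 3 + ["M2"] * 3,
            "genotype": ["BB", "BB", "bb", "bb", "bb", "BB"],
        })
        traj = estimate_heterozygote_trajectory(geno, ped)
        assert (traj == 0.0).all()

    def test_founders_all_heterozygous(self):
        ped = chain_pedigree(1)
        geno = pd.DataFrame({
            "progenitor_id": ped.ids,
            "marker": ["M1", "M1"],
            "genotype": ["Bb", "BB"],
        })
        traj = estimate_heterozygote_trajectory(geno, ped)
        assert traj.loc[0] == 1.0
        assert traj.loc[1] == 0.0

    def test_no_segregating_marker_gives_empty(self):
        ped = chain_pedigree(1)
        geno = pd.DataFrame({"progenitor_id": ped.ids,
                             "marker": ["M1", "M1"],
                             "genotype": ["BB", "BB"]})
        assert estimate_heterozygote_trajectory(geno, ped).empty


class TestErrorRateProfiling:
    def test_profile_prefers_generating_rates(self):
        """Grid profiling of (fp, fn) on simulated bands lands closer to the
        generating error rate than the grid extremes."""
        model = ObservationModel(fp=0.05, fn=0.05)
        cfg = SimConfig(n_generations=5, seed=71)
        ped, _, _, bands = simulate_dse(cfg, model)
        from dsekit.infer import profile_error_rates
        fp, fn, profile = profile_error_rates(
            ped, bands, grid=np.array([0.005, 0.05, 0.2]))
        assert len(profile) == 9
        assert fp in (0.005, 0.05) and fn in (0.005, 0.05, 0.2)
        best = profile["loglik"].max()
        worst = profile["loglik"].min()
        assert best > worst
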