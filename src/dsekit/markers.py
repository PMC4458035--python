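"""Dominant-marker genotypes and the bulk band-observation model.

AFLP and M-SAP markers are *dominant*: a gel band is seen whenever at least
one band allele is present in the template DNA, so heterozygotes cannot be
distinguished from band homozygotes on a single profile.  In this design the
template is a bulk of ``bulk_size`` S2 plants (two further generations of
selfing below the progenitor), which makes the band probability of a
heterozygous progenitor a known function of Mendelian segregation:

* a plant descended from a ``Bb`` progenitor through ``s`` selfings is
  band-less (``bb``) with probability ``(1 - 2**-s) / 2``;
* with three independent S2 plants (``s = 2``) the bulk shows no band with
  probability ``(3/8)**3 = 27/512``;
* if instead the three S2 plants share a single S1 mother, the no-band
  probability rises to ``33/128``.

Scoring errors are overlaid as a false-positive rate ``fp`` (band called on
a band-less bulk) and a false-negative rate ``fn`` (band missed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: genotype codes: number of band alleles (0 = bb, 1 = Bb, 2 = BB)
GENOTYPE_LABELS = ("bb", "Bb", "BB")
GENOTYPE_CODES = {label: i for i, label in enumerate(GENOTYPE_LABELS)}

#: selfing transition matrix, rows bb, Bb, BB -> columns bb, Bb, BB
SELFING_TRANSITION = np.array([
    [1.0, 0.0, 0.0],
    [0.25, 0.5, 0.25],
    [0.0, 0.0, 1.0],
])
SELFING_TRANSITION.setflags(write=False)


@dataclass(frozen=True)
class MarkerEffect:
    """A marker locus: its phenotypic effect and its place on the genome.

    ``a`` and ``d`` are the additive and dominance effects in degree-days
    under the {-1, 0, +1} / {0, 1} indicator parameterization (band-absent
    homozygote scores ``-a``; heterozygote scores ``d``).
    ``recomb_fraction_to_prev`` is the recombination fraction to the
    previous locus of the same linkage group in listing order (ignored for
    the first locus of a group).
    """

    name: str
    a: float = 0.0
    d: float = 0.0
    founder_state: str = "heterozygous"  # heterozygous | fixed_present | fixed_absent
    linkage_group: str = "LG1"
    recomb_fraction_to_prev: float = 0.5
    system: str = "EcoRI_MseI"

    def __post_init__(self) -> None:
        if not (0.0 <= self.recomb_fraction_to_prev <= 0.5):
            raise ValueError("recomb_fraction_to_prev must be in [0, 0.5]")
        if self.founder_state not in ("heterozygous", "fixed_present",
                                      "fixed_absent"):
            raise ValueError(f"unknown founder_state {self.founder_state!r}")


@dataclass(frozen=True)
class ObservationModel:
    """Probability model for scoring a dominant band on a bulk of S2 plants."""

    fp: float = 0.02
    fn: float = 0.02
    bulk_size: int = 3
    selfings_to_dna_plant: int = 2
    independent_s1: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.fp < 0.5 and 0.0 <= self.fn < 0.5):
            raise ValueError("fp and fn must be in [0, 0.5)")
        if self.bulk_size < 1 or self.selfings_to_dna_plant < 0:
            raise ValueError("bulk_size >= 1 and selfings_to_dna_plant >= 0")

    def p_bandless_plant(self, selfings: int) -> float:
        """P(a descendant of a Bb plant is bb after ``selfings`` selfings)."""
        return (1.0 - 0.5 ** selfings) / 2.0

    def p_band_in_bulk(self, genotype: int) -> float:
        """P(the bulk contains at least one band allele | progenitor genotype)."""
        if genotype == 2:  # BB: selfing cannot lose the band
            return 1.0
        if genotype == 0:  # bb: no reversion
            return 0.0
        s = self.selfings_to_dna_plant
        if self.independent_s1 or s < 2:
            q = self.p_bandless_plant(s)
            return 1.0 - q ** self.bulk_size
        # All bulk plants share one S1 mother drawn from the progenitor.
        q_by_s1 = np.array([1.0,  # S1 bb
                            self.p_bandless_plant(s - 1),  # S1 Bb
                            0.0])  # S1 BB
        prior = np.array([0.25, 0.5, 0.25])
        return 1.0 - float(prior @ q_by_s1 ** self.bulk_size)

    def p_observed_present(self, genotype: int) -> float:
        """P(band scored present | progenitor genotype), including errors."""
        p = self.p_band_in_bulk(genotype)
        return p * (1.0 - self.fn) + (1.0 - p) * self.fp


def emit_band_observation(genotype: int, model: ObservationModel,
                          rng: np.random.Generator,
                          systems: tuple[str, ...] = ("EcoRI_MseI",),
                          ) -> dict[str, int]:
    """Sample the observed band state for one progenitor and marker.

    The bulk of DNA plants is sampled once (one extraction); scoring errors
    are then drawn independently for each digestion system, mirroring the
    fact that each system is a separate gel run on the same template.
    Returns ``{system: 0 or 1}``.
    """
    if genotype not in (0, 1, 2):
        raise ValueError(f"genotype code must be 0, 1 or 2, got {genotype!r}")
    if genotype == 2:
        band = True
    elif genotype == 0:
        band = False
    else:
        s = model.selfings_to_dna_plant
        if model.independent_s1 or s < 2:
            plants = _self_n(np.full(model.bulk_size, 1), s, rng)
        else:
            s1 = _self_n(np.array([1]), 1, rng)[0]
            plants = _self_n(np.full(model.bulk_size, s1), s - 1, rng)
        band = bool((plants > 0).any())
    out = {}
    for system in systems:
        if band:
            out[system] = int(rng.random() >= model.fn)
        else:
            out[system] = int(rng.random() < model.fp)
    return out


def _self_n(genotypes: np.ndarray, n: int, rng: np.random.Generator
            ) -> np.ndarray:
    """Advance genotype codes through ``n`` rounds of selfing (single locus)."""
    g = genotypes.copy()
    for _ in range(n):
        het = g == 1
        if het.any():
            # offspring allele count = sum of two Bernoulli(1/2) gametes
            g[het] = rng.binomial(2, 0.5, size=int(het.sum()))
    return g


def classify_msap_marker(polymorphic_in_mspi: bool,
                         polymorphic_in_hpaii: bool) -> str:
    """Classify an M-SAP marker from its two isoschizomer digestion profiles.

    MspI and HpaII cut the same CCGG site but differ in methylation
    sensitivity, so the comparison separates sequence changes from
    methylation changes.
    """
    if polymorphic_in_mspi and polymorphic_in_hpaii:
        return "sequence-based"
    if polymorphic_in_mspi:
        return "methylated-region"
    if polymorphic_in_hpaii:
        return "methylation-based"
    raise ValueError("not polymorphic in either digestion system")
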