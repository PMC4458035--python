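"""Back-of-envelope expectations for polymorphism supply in a DSE.

Three small calculators put numbers on the "dearth of polymorphism"
argument: how many new mutations the gene space should have accumulated
over the experiment, how many polymorphisms residual heterozygosity implies
at the start, and how many of the known flowering-time QTLs are expected to
still segregate in a nearly fixed inbred line.
"""

from __future__ import annotations

#: maize gene-space size used throughout (base pairs)
GENE_SPACE_BP = 161e6


def expected_new_mutations(n_individuals: int = 10, n_generations: int = 16,
                           genome_bp: float = GENE_SPACE_BP,
                           mutation_rate: float = 3e-8) -> float:
    """Expected mutations arising in a population during the experiment.

    ``n_individuals`` progenitors maintained per population over
    ``n_generations`` generations, each transmitting a ``genome_bp`` gene
    space mutating at ``mutation_rate`` per base per generation.
    """
    return n_individuals * n_generations * genome_bp * mutation_rate


def initial_polymorphism_count(genome_bp: float = GENE_SPACE_BP,
                               residual_heterozygosity: float = 0.02
                               ) -> float:
    """Polymorphic sites implied by residual heterozygosity at the start."""
    return genome_bp * residual_heterozygosity


def expected_segregating_qtls(n_qtls: int = 100,
                              residual_heterozygosity: float = 0.019
                              ) -> float:
    """Flowering-time QTLs expected to segregate in a residually
    heterozygous inbred (close to a hundred QTLs are known for maize
    flowering time)."""
    return n_qtls * residual_heterozygosity
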