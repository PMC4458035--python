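# Methods

This note records the models behind `dsekit`, the defaults and why they
were chosen, and the limits of what the synthetic data can demonstrate.

## The experimental design being modeled

A divergent selection experiment (DSE) on a selfing crop: from the initial
seed lot of a nearly fixed inbred line, an Early and a Late population are
propagated by recurrent truncation selection.  Each generation, every
retained progenitor is selfed to produce ~100 seeds grown as 4 rows of 25
in a randomized block; the 3 most extreme plants of each row are tagged
(12 recorded plants per progenitor), and the 10 most extreme tagged plants
of the population become the next generation's progenitors.  Because a
progenitor has exactly one parent, the pedigree is a forest; families are
the lineages of individual founder plants.  An unselected control is grown
every year from S2 seed of the *initial* lot — crucially, it does not
propagate, so it carries no drift and anchors the year effects.

## Synthetic-data generator

`simulate.SimConfig` defaults encode that design directly: 6 generations
beyond the founders, 2 families per population, 10 progenitors kept, 100
offspring evaluated as 4×25, 3 selected per row, 12 plants phenotyped.

Genetics: the marker loci *are* the residual heterozygosity — founders are
heterozygous at every default locus, in coupling phase (all band alleles on
one haplotype), which is the configuration that produces the strong
within-group LD such experiments report.  Gametes recombine between
adjacent loci of a linkage group at the configured fractions and freely
between groups.  A plant's thermal-time phenotype is

    year_effect[year] + Σ_loci (a·x + d·y) + Normal(0, residual_sd)

with x ∈ {−1,0,+1} the band-allele count minus one and y the
heterozygosity indicator.  Defaults: six loci on two groups with |a| of
8–15 degree-days (the range reported for flowering-time-associated markers
in inbred maize selection lines), one dominance-only locus, residual sd
25 degree-days, year effects = 1100 degree-days ± a fixed ≤30 degree-day
seasonal pattern (silking thermal time of early-flowering maize under a
temperate climate).  Year effects are constants, not draws: the analysis
model treats year as fixed.

Band observation: DNA is a bulk of `bulk_size = 3` S2 plants.  A plant two
selfings below a `Bb` progenitor is band-less with probability
`(1 − 2⁻²)/2 = 3/8`, so the bulk of three independent S1 lineages misses
the band with probability `(3/8)³ = 27/512`.  Whether the three S2 plants
share one S1 mother is not determined by the assay description; both
variants are implemented (`independent_s1`, default true; shared-mother
no-band probability `33/128`).  Scoring errors are a false-positive rate
`fp` and false-negative rate `fn` (default 0.02 each — no external
calibration exists, and `infer.profile_error_rates` can profile them from
the data).  Control entries are not genotyped (only selected progenitors
entered the real assay).

What the generator does **not** emulate: seed-weight co-selection among
equally extreme plants (ties break uniformly at random — seed weight is
never analyzed downstream); new mutations arising during the experiment;
block effects within year (blocks are recorded but effect-free);
phenology–weather coupling (phenotypes are generated directly in thermal
time, `flowering_raw` is left missing).  Passing tests therefore show the
estimators recover what this model generates, not that real field data
meet the model's assumptions.  An optional hard phenotype ceiling
(`phenotype_ceiling`) reproduces the physiological limit where the latest
plants fail to set seed; it is off by default.

## Genotype inference

Each marker is inferred independently (markers are not co-estimated across
loci).  The joint likelihood over the pedigree factorizes into founder
priors (uniform over bb/Bb/BB — founder heterozygosity is inferred, not
assumed), selfing transmission terms (no reversion: homozygotes breed
true), and per-progenitor observation terms from the bulk model.  Because
every node has one parent, the global maximizer is computed *exactly* by
max-product dynamic programming on each tree — an upward Viterbi pass and
a downward backtrace.  Ties are broken deterministically: fewer
heterozygotes first (carried through the DP as a secondary objective),
then the smaller genotype under bb < Bb < BB at each node root-down.
The reported log-likelihood omits the constant uniform founder prior.

**Identifiability.**  Dominant markers cannot distinguish a `Bb` whose
bulk and whose descendants' bulks all show the band from a `BB`: the data
genuinely favor `BB` (its likelihood is 1).  Errors of the ML assignment
on simulated data are therefore concentrated in early-generation
heterozygotes with no band-absent descendants; on the default design this
caps overall per-entry accuracy near 93% (error-free scoring) while
homozygous-truth entries are called at ≥97%.  The same limit biases
*inferred* heterozygote trajectories downward at terminal generations, so
the decay-rate checks use the simulator's true genotypes.

The non-Mendelian filter discards a marker whose entire polymorphism rests
on a single progenitor's divergent band state unconfirmed by its parent or
any observed offspring (such singletons are indistinguishable from scoring
artefacts); a singleton in a terminal progenitor has no offspring to
confirm it and is retained with an `unconfirmed` flag instead.

## Selection response and heritability

Thermal time is a capped linear degree-day sum, `Σ max(0, min(T, To) −
Tb)` with Tb = 6 °C, To = 30 °C; the exact published conversion behind
those parameter values is not reproducible from its citation, so this
standard form is used and raw thermal-time input bypasses it.

Year correction fits `Z = Year_i + b_pop·gener` by least squares with the
Control slope pinned to zero.  When year and generation advance together
(the usual case), year effects and a common trend are confounded and the
control is what identifies the scale — a warning is emitted if the design
is confounded and no control is present.  The population-slope terms exist
only to de-confound the year estimates; the reported per-family responses
come from separate OLS fits of corrected `Y` on generation within each
family and analysis window (default windows G0–G6 and, when data reach
that far, G7–G16).  P-values are two-sided t-tests on the slope.

H² per family × generation comes from a one-way random-effects model with
progenitor as the random factor: REML via a linear mixed model, falling
back to the ANOVA method-of-moments estimator when the REML fit
degenerates (the two coincide for balanced designs).  Negative components
are truncated at zero, so Ĥ² ∈ [0,1] and its null distribution piles up at
0 (the L-shape seen in the per-generation summaries).  Family summaries
report the median and maximum over generations.

## Gene-dropping association

Breeding values are per-progenitor means of corrected flowering time,
centered by the per-generation mean μ_i of the analysis scope (global,
within-Early, within-Late; μ_i is computed once from the observed data and
not refitted per simulation).  Effects (a, d) are least squares of the
centered values on (x, y) via the pseudo-inverse, so a scope without
heterozygotes yields d = 0 rather than a failure.  The null distribution
drops two alleles from heterozygous founders through the pedigree under
the selfing transmission; each simulated genotype matrix is refitted
against the same observed breeding values.  P-values are two-sided on
|a| and |d| with the add-one rule `p = (1+k)/(n_eff+1)` — the magnitude
convention and the add-one estimator are choices (the sidedness of the
original test statistic is not documented anywhere), and simulations in
which the marker does not segregate within the scope are dropped from the
denominator with their count reported.  Progenitors with a missing
genotype are dropped from that marker's regression; nothing is imputed.

Note that *global-scope* effect estimates soak up population divergence:
any marker fixed for alternative alleles in Early vs Late tracks the whole
cumulative response, which is precisely why the within-population scopes
exist and why significance comes from gene dropping rather than from the
regression t-statistics.

## LD map

r² is the squared Pearson correlation of per-progenitor band frequencies
(bb→0, Bb→0.5, BB→1) over pairwise-complete progenitors; constant markers
get missing entries with a warning.  Pair significance is by permuting one
vector across progenitors (add-one P-values).  Linkage groups are
single-linkage components of the graph with edges p ≤ α; α defaults to
0.001, a deliberately conservative Bonferroni-flavored choice for tens of
markers at ≥999 permutations (both α and the linkage rule are
configurable).  Within a group, the order is chosen by a rank-dispersion
criterion: within-group r² values are converted to ranks (average ranks on
ties) and the objective is the summed variance of ranks among pairs
separated by the same number of intervals — under the true order, equal
interval counts should have similar LD.  Search is exhaustive over orders
up to reversal for groups of ≤8 markers and multi-start hill climbing
(segment reversals + pairwise swaps, seeded) beyond; the returned order is
canonicalized so its first label sorts before its last.  Map distances
between neighbors are `d = −ln r²` (natural log), treated as additive; an
adjacent r² of zero gives an infinite distance and a split flag.

Divergent selection itself generates LD between physically unlinked loci
that fix in opposite directions by population, so on strongly selected
simulated data the grouping reflects co-selection as much as physical
linkage — the same caveat applies to the real assay.

## AMOVA

Progenitor band-frequency profiles are points in marker space; total sum
of squares (equal to the half-mean of squared Euclidean pairwise
distances) is partitioned exactly into among-population,
among-family-within-population and within-family terms.  Variance
components come from the nested expected mean squares with the standard
unequal-size coefficients; percentages are components over their sum.
Missing frequencies are mean-imputed per marker with the count reported;
Control progenitors are excluded (they are outside the selection
hierarchy).  Significance: the among-population component is tested by
permuting progenitor rows against the whole label structure, the
among-family component by permuting rows within populations; both use
add-one P-values.  Data are pooled across generations by default (a
per-generation analysis is a matter of subsetting the frequency matrix).

## Pipeline and reproducibility

All stage seeds derive from one root seed through `SeedSequence`, and a
rerun with the same config is byte-identical.  The run manifest records
the config hash, seeds, package version and output paths.  The library
functions and per-stage subcommands are the interface; `dsekit run`
orchestrates them.

## Numerical and testing notes

* Impossible configurations get −∞ log-likelihood; tuple comparison keeps
  the DP exact in their presence.  DP optimality is verified against
  brute-force enumeration over all 3ⁿ assignments on random pedigrees.
* The bulk band probabilities (485/512, 95/128, …) are verified against an
  independent exhaustive enumeration of selfing outcomes.
* Permutation and gene-dropping nulls are checked for uniformity with
  ~200 independent null statistics each; calibration checks use
  independent replicates (fresh null phenotypes per marker) because shared
  references correlate the statistics and inflate the variance of the
  rejection rate without biasing its mean.
* Simulation sizes in the tests (4–6 generations, 3–10 progenitors kept,
  tens to hundreds of seeded replicates) are chosen so the whole suite
  runs in well under a minute while keeping Monte-Carlo standard errors
  small relative to the asserted tolerances.

## Known limitations

* Single-parent pedigrees only; no outcrossing, no multi-allelic markers.
* Each locus is inferred independently; linked loci are not co-estimated.
* The rank-dispersion ordering objective is this package's concrete
  operationalization of "similar LD ranks per interval" — it provably
  recovers exponential-decay chains in the tests, but it is one of several
  reasonable statistics.
* Global association estimates confound locus effects with population
  divergence by construction (see above).
* H² here is broad-sense and within-family; no realized heritability or
  kinship-based mixed models.
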