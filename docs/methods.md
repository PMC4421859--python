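# Methods

## The analysis model

The package treats three organism-level quantities as jointly structured:
body mass M [g], mass-specific metabolic rate q = B/M [W/g], and a genome
summary — either genome size [bp] or the proportion of genes in a
functional category.  The working hypotheses are

* allometry: q ∝ M^(−β), estimated by ordinary least squares of log₁₀ q on
  log₁₀ M (β = −slope, with its OLS standard error).  Base-10 logs are
  used; switching to natural logs leaves β and its SE unchanged, and
  rescaling all masses by a constant moves only the intercept.
* functional content: the proportion of *oxic* genes — genes linked via
  pathway (KGML) gene→reaction annotations to at least one reaction from a
  curated list of reactions that occur in the presence of oxygen — carries
  signal about q and about maximal lifespan beyond what body mass explains.
* genome size: its marginal correlation with q is expected to be a mass
  artefact, vanishing once mass is controlled.

All dependence measures are rank-based.  Spearman's r_s is the Pearson
correlation of mid-rank vectors (ties receive average ranks; tie handling
alters third decimals, so it is fixed throughout and matches the common
convention).  The body-mass-controlled association is the first-order
partial on ranks,

    r_xy.z = (r_xy − r_xz·r_yz) / √((1 − r_xz²)(1 − r_yz²)),

which equals the precision-matrix definition −P_xy/√(P_xx·P_yy); the test
suite verifies the two routes agree to 1e-10.  Two-sided p-values use the
t approximation t = r·√((n−2−k)/(1−r²)) on n−2−k degrees of freedom
(k = number of controllers).  For the simple coefficient at n ≤ 8 the
p-value is instead exact, computed over all n! pairings — at such sizes
the t approximation is the larger error term and full enumeration costs
microseconds.  The partial coefficient always uses the t approximation: a
permutation null for a partial correlation requires a conditional
permutation scheme and is deliberately out of scope.  p-values below
2.2e-16 are printed as "< 2.2e-16" in text output but stored as computed.

The category screen computes, for every functional-category proportion
(oxic metabolism included as a pseudo-category), the simple and the
mass-controlled partial correlation with q on the same organisms, retains
categories with partial p < α (α = 0.05, raw p-values — the screen is
deliberately uncorrected; Benjamini–Hochberg q-values are attached for
reference), and sorts by partial coefficient descending.  Constant or
rank-degenerate categories are dropped with a warning rather than aborting
the screen, which matters at very small n.

## Trait-table conventions

Measurements are converted to W, W/g, g, °C and years on ingest.  Species
are collapsed to genus means (arithmetic by default; a geometric-mean
switch exists for sensitivity analysis, temperature always averaging
arithmetically since it can be ≤ 0 °C).  A field missing in some genus
members is averaged over the members that have it, and is missing at genus
level only when no member has it.  When no member carries a pre-computed
q, the genus q is derived from the averaged B and M (the two paths differ;
the derivation is logged when taken).  Each genus is represented by the
genome completed earliest; ties on year break lexicographically by genome
code and are logged.  Genus averaging is permutation-invariant and
idempotent.

## Temperature correction

Two corrections to a common reference X [°C] are implemented:

* Q10-style: q_X = q × 10⁻³ × 2^((X−T)/10), assuming a rate doubling per
  10 °C.  The 10⁻³ prefactor is kept exactly as conventionally printed;
  it is a common positive factor and cannot influence any rank statistic.
  Note that for this form, corrections to two different targets differ
  only by the global constant 2^((X₁−X₂)/10), so every rank statistic is
  *identical* across targets; divergent results at 25 °C vs 10 °C can only
  arise from the Boltzmann form or from differing organism subsets.
* Boltzmann–Arrhenius: q_X = q × exp[−E/k (1/(X+273.15) − 1/(T+273.15))],
  k = 8.6173 × 10⁻⁵ eV/K, activation energy E defaulting to 0.65 eV, the
  accepted average for enzyme-catalysed reactions.  Values outside the
  plausible range [0.4, 0.8] eV require an explicit override.

Both corrections are multiplicative in q and therefore rank-preserving
whenever all organisms share one measurement temperature.  Ectothermic
vertebrates do not hold a body temperature near the reference points, so
they — and organisms lacking a measured temperature — are excluded from
the temperature-corrected analyses, with counts logged.

## The synthetic panel generator

The generator emulates the study conditions of a prokaryote-to-mammal
comparative panel with every effect planted and recorded:

* 101 genera (one species each by default); genus log₁₀ masses drawn
  uniform over [−13, 6] (≈10 fg bacterium to multi-tonne mammal).  Taxon
  labels (59% prokaryote, 9% protozoan, 5% insect, 4% ectothermic
  vertebrate, 6% bird, 12% mammal) are assigned by mass-order strata so
  labels stay mass-consistent while rank(M) remains an affine function of
  log₁₀ M.  That affinity is load-bearing: with clustered (e.g.
  taxon-windowed) mass draws, rank(mass) becomes a nonlinear transform of
  log-mass and the *linear-in-ranks* partial no longer fully removes mass,
  leaving spurious genome–rate partials under the null.
* genome size: log₁₀ G = 6.4 + 0.163·(log₁₀ M + 13) + N(0, 0.6), clipped
  to [5.5, 10.5] — ~2.5 Mb microbial to ~3 Gb vertebrate genomes, with a
  mass–genome rank correlation ≈ 0.83.
* oxic proportion: 0.12 + 0.002·(log₁₀ M − mid) + N(0, 0.06), truncated
  to [0.005, 0.95] (a target above 1 is an error).
* rate: log₁₀ q = −2 − β·log₁₀ M + e·(oxic − 0.12) + N(0, 0.3), with
  β = 0.035 and e = 2.9 per unit oxic proportion.
* lifespan (mammals and birds only): log₁₀ L = 0.5 + 0.2·log₁₀ M
  − 2.5·(oxic − 0.12) + N(0, 0.15) — mass helps, oxic content costs.
* 30 decoy categories whose proportions are lognormal noise around fixed
  bases in [0.01, 0.06], independent of every trait.
* temperatures: mammal body temperatures ≈ N(38.5, 0.8) °C, other
  temperature-bearing taxa ambient U(2, 40) °C; birds and insects carry no
  temperature (mirroring availability patterns in trait compilations), so
  the default panel yields ~84–86 temperature-eligible organisms.
* mode of life: birds volant; mammals volant with probability 3/23 (bats),
  giving lifespan panels of roughly 10 volant / 20 non-volant organisms.

A note on calibration: in a trivariate rank structure the four headline
quantities — r(q,M), r(oxic,M), r(q,oxic) and the partial r(q,oxic·M) —
are tied together by the first-order formula, so they cannot be planted
independently.  The defaults realise a strongly negative q–mass
correlation (≈ −0.4), a mass-controlled oxic partial ≈ +0.45, a robustly
positive marginal r(q,oxic) ≈ +0.33, and a weakly positive oxic–mass link
(≈ +0.2); the last is the quantity sacrificed to keep the other three
simultaneously realisable.

Gene-level annotations *realise* every proportion exactly: the target is
rounded to an integer gene count over the organism's total (500–20 000
genes, scaling with log genome size) and the realised count/total — not
the target — feeds the trait model, so profiles recomputed from the
written KGML/`.keg`/FASTA fixtures equal the generator's internal values
bit for bit.  Genes in no decoy category fall into an "Unclassified"
heading so the annotation universe always covers the genome.  A
configurable fraction of category genes (default 10%) is drawn from a
shared pool, producing multiply-categorised genes as real hierarchies
have.  Everything is deterministic given the seed, including fixture
bytes; annotation gene sets use per-organism child streams so trait values
do not depend on whether annotations are materialised.

What the generator does **not** emulate: phylogenetic autocorrelation
(organisms are exchangeable given mass), real pathway topology or gene
identifiers, correlated decoy categories (real BRITE categories overlap
and co-vary; multicollinearity across categories is therefore untested),
measurement error in mass, and taxon-specific allometric slopes.  Passing
recovery tests consequently show the *estimators* are correct and
calibrated under the stated conditions — not that real comparative data
satisfy those conditions.

## Numerical choices

* Rank ties: average ranks everywhere, matching the common convention.
* Degenerate inputs: constant vectors are errors for the core statistics;
  orchestration layers (screen, pipeline report) degrade per-item with a
  warning and an error record instead of aborting.  A controller whose
  ranks determine a variable (|r| = 1) is an error for the partial.
* The partial coefficient is clipped to [−1, 1] after the division to
  absorb last-bit floating-point overshoot.
* Pipeline analyses require n ≥ 4; n < 8 triggers a low-power warning.
* Gene counts below 2 per decoy category are raised to 2 so tiny genomes
  cannot produce constant category columns by construction.
* BRITE parsing defines "level 2" as the `B` lines of a `.keg` file; gene
  lines are the deepest letter tier present.  The proportion denominator
  defaults to the distinct genes in the hierarchy file, switchable to a
  genome-wide gene list (`--denominator genome`) since either convention
  is defensible.
* Problem sizes in the test and acceptance runs (e.g. 50-seed recovery
  loops, 30-panel calibration, 3-organism round-trip fixtures) were chosen
  as the smallest sizes at which the binomial/recovery bounds are
  meaningful.

## Known limitations

* No phylogenetically independent contrasts or comparative regression —
  genus averaging is the only redundancy control, by design.
* The screen's raw-p retention reproduces a conventional analysis plan;
  the attached BH q-values show how much of it survives correction.
* The exact-permutation p is limited to the simple coefficient and n ≤ 8.
* Q10-style correction cannot distinguish reference temperatures in any
  rank analysis (see above); use the Boltzmann form for that question.
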