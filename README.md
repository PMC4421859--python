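# oxilink

Comparative-genomics tooling that asks whether *what* a genome encodes —
rather than how large it is — tracks two classic physiological parameters:
mass-specific metabolic rate and maximal lifespan.

Across organisms from prokaryotes to mammals, metabolic rate B [W] scales
with body mass M [g], and the mass-specific rate q = B/M [W/g] follows a
power law q ∝ M^(−β).  Genome size correlates with q too, but both are
mass-linked, so the question is what survives once mass is controlled.
`oxilink` computes, for each organism, the proportion of genes in every
functional category of a KEGG BRITE-style hierarchy — including *oxic
metabolism*, the genes linked through KEGG pathway (KGML) annotations to at
least one reaction that occurs in the presence of oxygen — and screens
those proportions against q and against maximal lifespan with Spearman rank
correlations and first-order, body-mass-controlled partial rank
correlations:

    r_xy.z = (r_xy − r_xz·r_yz) / √((1 − r_xz²)(1 − r_yz²))

Rates measured at different temperatures are rescaled to a common reference
either Q10-style, q_X = q × 10⁻³ × 2^((X−T)/10), or by Boltzmann–Arrhenius,
q_X = q × exp[−E/k (1/(X+273.15) − 1/(T+273.15))] with E = 0.65 eV.  The
allometric exponent β is estimated by OLS of log₁₀ q on log₁₀ M.

Because the trait compilations and licensed genome annotations behind such
studies cannot be redistributed, the package ships a synthetic panel
generator (`oxilink.synthetic`) that emulates them — planted power-law
scaling, a mass-linked genome size, an oxic-proportion effect on rate and a
negative one on lifespan, decoy categories of pure noise — and writes
schema-faithful KGML / `.keg` / FASTA / TSV fixtures so the entire pipeline
runs offline with known ground truth.

Audience: comparative physiologists and genome scientists who want a
reproducible, testable implementation of this analysis plan to run on their
own trait tables and annotation exports.

## Worked example

Simulate a 40-genus panel, build profiles from the written annotation
files, and run the analysis:

```sh
oxilink all --seed 11 --out demo --n-genera 40 --n-categories 10 \
    --genes-min 200 --genes-max 2000
```

prints (abridged):

```
organisms analysed: 40
  allometric exponent beta = 0.041 ± 0.010 (n = 40)
  q vs body mass: r = -0.565, p = 0.000147, n = 40
  q vs genome size: r = -0.470, p = 0.00219, n = 40
  q vs genome size | mass: r = -0.040, p = 0.81, n = 40
  q vs oxic proportion: r = +0.266, p = 0.0968, n = 40
  q vs oxic proportion | mass: r = +0.448, p = 0.00421, n = 40
  categories retained at p < alpha: 2
    Oxic metabolism: r_s^p = +0.448 (p = 0.00421)
```

Read bottom-up: genome size looks informative (r = −0.47) until body mass
is held constant (r = −0.04, p = 0.81) — its apparent signal is a mass
artefact.  The oxic gene proportion shows the opposite pattern: modest
marginally, but clearly positive once mass is controlled (r = +0.45,
p = 0.004), and it tops the category screen.  The fitted β = 0.041 ± 0.010
recovers the planted shallow exponent (0.035) within one standard error.
`demo/analysis/report.json` holds the full machine-readable report and
`demo/analysis/screen.tsv` the per-category table.

The same analyses run on your own data via
`oxilink profile --annotations DIR --oxic LIST.tsv --out P` followed by
`oxilink analyze --traits TRAITS.tsv --profiles P/profiles_matrix.tsv --out A`.
The trait-table header is documented in `oxilink.traits.TRAIT_COLUMNS`.

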