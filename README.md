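# zeapop

Population-genomic analysis of North American *Helicoverpa zea* (corn
earworm), built for studying how insecticide exposure reshapes a pest
genome: detection of interspecific introgression from *H. armigera*,
connectivity and isolation-by-distance testing across sampling sites, a
composite-likelihood selective-sweep scan with selection-coefficient
estimation, and deterministic modelling and fitting of resistance-allele
trajectories. The package ships first-class synthetic-data generators so
every stage is testable end-to-end without access to the original
resequencing data. It is aimed at population geneticists and resistance-
management researchers working with multi-sample VCFs.

## What it computes

* **Introgression** — frequency-based ABBA–BABA statistics in sliding
  windows. For derived-allele frequencies (p1, p2, p3, pO) in the reference
  population, test population, candidate donor and outgroup,
  ABBA = (1−p1)·p2·p3·(1−pO), BABA = p1·(1−p2)·p3·(1−pO),
  D = Σ(ABBA−BABA)/Σ(ABBA+BABA), and fd̂ = Σ(ABBA−BABA)/Σ(ABBA_D−BABA_D)
  (donor terms substitute pD = max(p2, p3)), including per-individual fd̂
  that pinpoints which samples carry donor tracts.
* **Windowed summary statistics** — nucleotide diversity π, divergence dxy,
  and Hudson FST (ratio of averages), plus composite-LD decay and Welch
  segment contrasts.
* **Isolation by distance** — FST/(1−FST) regressed on ln(great-circle km)
  over all deme pairs, with one-sided Pearson tests; no signal at low FST
  indicates effective panmixia.
* **Sweep scan** — a CLR test of the unfolded site-frequency spectrum
  against an escape-and-drag hitchhiking model on a 1 kbp grid, maximized
  over the sweep intensity α, with region clustering, a locus-overlap
  permutation test, and ŝ = r·ln(2Ne)/α̂ using Ne = θπ/(4μ).
* **Selection trajectories** — the single-locus recursion with dominance
  (wAA = 1, wAa = 1+hs, waa = 1+s), calendar-time retrodiction, and a
  uniform random-search fit of (s, h) to observed allele frequencies.
* **Variant QC and coding effects** — the published filter stack (QUAL,
  depth, missingness, singletons, exact Hardy–Weinberg screen, Z-linked
  heterozygosity association screen), genotype-confidence thresholds,
  proxy-SNP selection, and synonymous/nonsynonymous/stop-gain classification
  with a biochemical-property flag.

See `docs/methods.md` for model details, assumptions and design choices.

## Worked example

Estimate the strength of selection behind a sweep and ask whether it can
explain two decades of allele-frequency change:

```python
>>> import zeapop as z

>>> ne = z.estimate_ne(theta_pi=0.0346, mu=8.4e-9)
>>> round(ne.Ne)
1029762

>>> s = z.estimate_s(alpha_hat=1.6195e-5, r=5.447e-8, Ne=ne.Ne)
>>> round(s, 4)
0.0489

>>> traj = z.predict_calendar(q0=0.1, year0=1998, year_end=2019,
...                           gens_per_year=10, s=0.0508, h=1.0)
>>> round(traj["q"].iloc[-1], 3)
0.864
```

A diversity of θπ = 0.0346 at mutation rate 8.4×10⁻⁹ gives an effective
population size of ~1.03 million. A sweep of fitted intensity
α̂ = 1.6195×10⁻⁵ on a chromosome with mean recombination rate
5.447×10⁻⁸/bp then implies a selection coefficient of about 0.049 — strong
selection. Iterating the recursion for a dominant allele from frequency 0.1
in 1998 at ten generations per year carries it to 0.864 by 2019, i.e. this
single coefficient plausibly explains near-fixation within two decades.

Fitting the model to observed frequencies instead:

```python
>>> obs = z.gen_trajectory_observations(s=0.05, h=1.0, q0=0.1,
...                                     years=[1998, 2002, 2017])
>>> fit = z.fit_selection(obs, gens_per_year=10, h="free",
...                       n_iter=100_000, seed=2)
>>> round(fit.s_fit, 3), round(fit.h_fit, 3)
(0.05, 0.994)
```

The random search recovers both the generating selection coefficient and
near-complete dominance.

A command-line layer mirrors the library
(`zeapop simulate|qc|windows|introgression|ibd|sweep|trajectory ...`); each
subcommand reads VCF + metadata TSV and writes TSV/BED/JSON.

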