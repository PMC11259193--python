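# Methods

This note documents the models implemented in `zeapop`, the assumptions they
make, the synthetic data the package generates to exercise them, and the
numerical and design choices that were genuinely open.

## Scope and data model

The package analyses biallelic SNP genotypes for North American *Helicoverpa
zea* and related *Helicoverpa* species: interspecific introgression
(ABBA–BABA fd̂), connectivity and isolation by distance, a
composite-likelihood selective-sweep scan with selection-coefficient
estimation, and deterministic selection-trajectory modelling. The common
currency is a `GenotypeDataset`: ordered sites (chrom, 1-based position, REF,
ALT, ancestral allele, phred QUAL) with a diploid dosage matrix in
{0, 1, 2, missing} and per-genotype depth. Sample metadata map each sample
to an analysis group (P1/P2/P3/outgroup), a deme, coordinates and a
collection year. VCF 4.2 is the on-disk format (unphased GT, per-genotype
DP, ancestral allele in INFO/AA); reading goes through cyvcf2.

## Variant QC

Filters run in a fixed, reported order: per-genotype depth masking
(genotypes at depth < 2 or > 200 become missing) precedes the site-level
filters, because singleton status depends on the genotypes left after
masking; then site QUAL < 20, site mean depth outside [2, 200], missingness
> 50%, non-biallelic records, and finally singletons (minor allele count
exactly 1 over non-missing genotypes). The filter report counts removals per
rule in application order, so the counts sum to sites-in minus sites-out and
the whole operation is idempotent.

The Hardy–Weinberg screen uses the exact conditional (Levene/Haldane) test —
the sum of probabilities of all heterozygote counts, given the observed
allele counts, whose probability does not exceed the observed configuration's
(no mid-p correction). Within each group it tests only sites with no missing
genotypes in that group, and a site is removed when it violates HWE
(p < 0.01) in at least two groups.

The Z-heterozygosity association screen guards against sex-linked reads
mismapped to autosomes: per-sample heterozygosity on Z-linked scaffolds is
regressed (ordinary least squares) on each autosomal SNP's dosage, and SNPs
whose slope-test p-value falls in the smallest 1% of testable SNPs
(boundary ties included) are removed. A constant trait vector makes every
slope untestable; the dataset is returned unchanged with a warning flag.

Genotype-confidence thresholds convert a confidence level to a phred value
as −10·log₁₀(1 − level), e.g. 0.95 → 13.0103. The proxy-SNP rule selects,
within a locus interval and subject to ≤ 25% missingness, the SNP with the
lowest major-allele frequency (ties to the lowest coordinate) — the site
least likely to owe its frequency to genotyping error when all candidates
are near fixation. A mapping-bias screen based on read-level statistics
(e.g. rank-sum tests on mapping quality) is out of scope: it requires
read-level data the package does not model.

## Windowed statistics

Per-site estimators are missing-data aware and summed over tiled windows
aligned to multiples of the window size (20 kbp and 100 kbp are the standard
classes, requiring at least 200 and 100 informative sites respectively;
sub-threshold windows are reported missing, never zero):

* π per site: 2·i·(n−i)/(n·(n−1)) for derived count i among n non-missing
  chromosomes; the window value divides the per-site sum by the window's
  callable length (configurable; the window length by default).
* dxy per site: pA(1−pB) + pB(1−pA); same denominator.
* FST: the Hudson estimator as a ratio of averages,
  Σ[(pA−pB)² − pA(1−pA)/(nA−1) − pB(1−pB)/(nB−1)] / Σ[pA(1−pB) + pB(1−pA)],
  the form recommended for window data. Other FST conventions differ by a
  small constant; comparisons across estimators should not mix them.

LD decay uses the squared Pearson correlation of dosage vectors (composite
LD), appropriate for unphased data; pairs are binned by physical distance
and the smallest bin at or below a stated background r² is reported.
Segment contrasts use the Welch unequal-variance t test with Satterthwaite
degrees of freedom.

## Introgression statistics

Site patterns are computed from derived-allele frequencies (p1, p2, p3, pO)
with ABBA = (1−p1)·p2·p3·(1−pO) and BABA = p1·(1−p2)·p3·(1−pO); the
donor-normalization terms substitute pD = max(p2, p3) for both p2 and p3.
Windowed D = Σ(ABBA−BABA)/Σ(ABBA+BABA); fd̂ = Σ(ABBA−BABA)/Σ(ABBA_D−BABA_D)
estimates the admixed fraction of a window. Polarization takes the outgroup
major allele as ancestral when its frequency reaches 0.8 (configurable);
sites in between are treated as unpolarizable and dropped, as are sites with
fewer than two non-missing chromosomes in any of P1, P2, P3. fd̂ is reported
missing where D ≤ 0 (it is not meaningful there); a zero-fill flag exposes
the genome-scan convention of reporting 0 instead, which is the convention
used when summarizing whether a null distribution is centred on zero.
Per-individual fd̂ uses a single diploid as P2, so p2 ∈ {0, ½, 1}.

A caveat documented here because it shapes the tests: at sites that are not
species-diagnostic, a heterozygous or alternate-homozygous individual call
(p2 > p3) contributes to the fd̂ denominator but not, in expectation, to the
numerator. When diagnostic sites are a small fraction of SNPs this attenuates
per-individual fd̂ toward ~0.5 in fully introgressed windows. Between
well-diverged species the diagnostic fraction of called SNPs is high
(between-species divergence exceeds within-species diversity severalfold),
so the package's tract-recovery tests use a generator divergence of 0.5,
while the admixture-fraction test (pool fd̂ ≈ fraction of admixed samples)
uses 0.05 where the attenuation is immaterial.

## Connectivity and isolation by distance

Pairwise deme distances use the haversine great-circle formula on a sphere
of mean radius 6371.0088 km (an ellipsoidal geodesic would differ by
< 0.5%). Pairwise differentiation is the unweighted mean of non-missing
20 kbp window FST values. The regression follows the lattice-model
linearization: FST/(1−FST) on ln(km), with the slope, Pearson r, and one- and
two-sided p-values reported. Deme pairs are not independent; the parametric
test is reported as-is (no Mantel permutation), and this caveat applies to
any interpretation of the p-value. The log base affects only the slope
scale, not r or p.

## Selective-sweep scan

The scan is a composite-likelihood ratio test on the unfolded SFS. The
background spectrum is estimated genome-wide from outgroup-polarized sites
(outgroup consensus threshold 0.8); sites at a smaller sample size than the
common n enter via the hypergeometric likelihood of their observed count,
and the background is projected down (hypergeometric expectation) to each
site's n during scanning, so no site is dropped.

The sweep model is the escape-and-drag approximation. At distance d bp from
a sweep of intensity α per bp, each of n sampled lineages escapes the
sweeping haplotype with probability p_e = 1 − exp(−α·d). Conditional on e
escapees, m = e + 1 exchangeable lineages (the escapees plus the sweeping
ancestor) are drawn from the background by projection; the ancestor is a
uniformly chosen one of the m and its allelic state is copied to the n − e
dragged lineages, so with j derived among m the final derived count is
j − 1 + (n − e) with probability j/m and j otherwise. The mixture over
Binomial(n, p_e) escape counts is conditioned on polymorphism
(1 ≤ k ≤ n − 1). Only polymorphic sites are modelled — invariant-site and
post-sweep-mutation classes present in some published scan tools are
deliberately omitted, so CLR values are not bit-comparable with those tools.
α is the compound parameter r·ln(2Ne)/s, giving the selection-coefficient
estimate s = r·ln(2Ne)/α̂ from the per-chromosome mean recombination rate r
and effective size Ne.

At each 1 kbp grid position, CLR(x) = 2·(max_α Σᵢ log P(kᵢ | α, |posᵢ − x|)
− Σᵢ log P_bg(kᵢ)), floored at zero. Because the distorted spectrum depends
on (α, d) only through α·d, the scan precomputes log-probabilities on a
1200-point log-spaced α·d grid (spanning 10⁻¹⁰–10⁵; resolution ≈ 2.5% in
α·d) and maximizes over a 41-point log grid of α on [10⁻⁸, 10⁻¹] with
parabolic refinement of the grid optimum on the log-α axis. Golden-section
refinement was considered and rejected: the table makes the objective
piecewise-constant in α·d, which defeats bracketing; the combined grid
resolution is far finer than the factor-of-3 recovery the scan is asked to
deliver. Candidate regions take the 99.99th percentile of grid CLR values as
threshold (ties included), merge above-threshold positions within 20 kbp,
and extend each cluster 20 kbp on both sides, clipped to chromosome bounds.
The fixed ±20 kbp padding is an annotation convention; when measuring how
much of a null scan is flagged, the unpadded cluster cores are the
meaningful quantity. The locus-overlap permutation test places equal-length
intervals uniformly within the scanned span and reports
p = (1 + #{null ≥ observed})/(n_perm + 1) for both the mean and the maximum
CLR over covered grid points.

## Selection trajectories

The single-locus deterministic model assigns fitnesses wAA = 1,
wAa = 1 + h·s, waa = 1 + s (A ancestral, a derived) and iterates
Δp = p·q·[p·(wAA − wAa) + q·(wAa − waa)]/w̄ with
w̄ = p²·wAA + 2pq·wAa + q²·waa, advancing q' = q − Δp. Calendar predictions
run (year_end − year0) × gens_per_year generations starting at year0; the
year-counting convention is inclusive-exclusive, and alternative conventions
shift an end-of-series frequency by roughly one generation's Δq — the reason
retrodicted end-of-series values carry a band rather than a point in the
tests. Effective population size comes from Ne = θπ/(4μ) with default
μ = 8.4 × 10⁻⁹ per bp per generation (the widely used *Drosophila* rate;
this value is required for consistency between the published θπ = 0.0346 and
the published Ne ≈ 1.03 × 10⁶ — an inconsistently printed exponent
elsewhere is resolved in favour of the arithmetic). Recombination-unit
conversions solve ρ = 4Ne·c and apply the Haldane map function
cM/bp = 50·ln(1/(1 − 2c)), defined for c < 0.5.

Fitting draws (s, h) uniformly at random (h optionally fixed), anchors the
trajectory at the first observation, and scores each draw as 1 − mean
|observed − expected| over the remaining observation years, returning the
best draw with its seed. The mean (rather than the sum) of absolute errors
keeps the score in [0, 1] regardless of the number of observation years.
The search is vectorized across draws, so 10⁵–10⁶ iterations cost seconds.
No stochastic (diffusion-likelihood) inference is attempted, and the only
uncertainty statement available is seed replication.

## Coding effects

Coding regions carry the genomic-forward exon sequence; the spliced CDS is
the exon concatenation, reverse-complemented for minus-strand genes, and
translation uses the standard nuclear codon table. SNP effects substitute
the variant base in the spliced frame (strand-aware) and re-translate the
affected codon: synonymous, nonsynonymous, stop_gain or stop_loss. The
biochemical-property flag uses a five-class partition — nonpolar
{A,V,L,I,M,F,W}, polar-uncharged {S,T,C,Y,N,Q}, positive {K,R,H}, negative
{D,E}, special {G,P} — chosen as a standard and documented convention (the
partition is configurable by editing the table; any partition choice is
somewhat arbitrary at the boundaries, e.g. G and C). The variant report
keeps nonsynonymous, property-changing SNPs with alt-allele count ≥ 2,
masking sites whose QUAL falls below the 95%-confidence threshold (13.0103);
the dataset carries site-level confidence, so masking is per-site rather
than per-genotype, and frequencies use the confidently called chromosomes at
each site as denominator (so frequency × chromosomes is an integer).
Indels and multi-nucleotide substitutions are not considered.

## Synthetic data: what it emulates and what it does not

Every generator is a pure function of (scenario, config, seed).

* **Neutral background.** Derived counts are drawn from the neutral 1/i law
  over 1..2n−1 and assigned to haplotypes uniformly; positions are uniform
  without replacement, sorted, 1-based in VCF. Sites are exchangeable and
  unlinked: the CLR scan consumes only the SFS, so this gives exact control
  of the null without coalescent machinery. There is no LD, no recombination
  map, and no mutation-rate variation.
* **Sweep spike.** Site counts are re-drawn from the same escape-and-drag
  spectrum the scan fits, at each site's distance from the focal position.
  Generator and inference form a self-consistent pair: recovery tests
  demonstrate correctness of the implementation, not robustness of the model
  to demography, background selection, or soft sweeps.
* **Structured demes.** Per site, an ancestral frequency is drawn from the
  neutral law over a notional pool; each deme's frequency is
  Beta(p(1−F)/F, (1−p)(1−F)/F) with F given by the scenario's map of the
  deme's distance from the first deme, and genotypes are Hardy–Weinberg
  binomial within demes. Draws are independent across demes, so pairwise
  differentiation reflects the two demes' F values rather than their mutual
  distance; isolation-by-distance fixtures therefore place demes at
  geometrically increasing distances along a line, which makes pairwise
  distance an effective ordering of pairwise differentiation. No migration
  matrix or spatial autocorrelation is modelled.
* **Introgression.** Recipient (P1, P2) and donor (P3) pools share ancestral
  polymorphism; a fraction `divergence` of sites are fixed differences
  (donor derived, recipients ancestral); the outgroup is fixed ancestral.
  Designated P2 individuals carry the donor allele at diagnostic sites
  within their tract intervals on one or two haplotypes, and the injected
  tracts are recorded in the metadata. Tracts are deterministic intervals,
  not recombination-broken mosaics.
* **Trajectories.** The deterministic recursion, with optional binomial(2N)
  drift per generation and binomial(n_chrom) observation noise per listed
  year; both off by default, matching the deterministic model.

Passing tests on these fixtures show the estimators compute their defining
formulas correctly and recover parameters the generators control; they do
not show robustness to linkage, demographic history, or genotyping error
beyond the modelled missingness and depth fields.

## Problem sizes and numerical conventions

Default test-scale problem sizes: 1 Mbp regions, 2,000–20,000 SNPs, 10–100
diploids, 1 kbp scan grid, 10⁵ random-search iterations; these suffice for
the parameter-recovery tolerances quoted in the test suite (peak within
50 kbp, α̂ and ŝ within a factor of 3, s_fit within ±0.002). Spectra are
renormalized after conditioning (sum-to-one enforced to < 10⁻¹²); escape
probabilities are floored at 10⁻³⁰⁰ to avoid log-domain underflow at d = 0;
the exact HWE test compares class probabilities with a 10⁻¹² relative
tolerance when accumulating the tail. Percentile thresholds include boundary
ties throughout.
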