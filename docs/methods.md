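# Methods

This note records the models, estimators, numerical choices and known
limitations behind `parshift`, in the spirit of a package methods
appendix. Units: map positions in centimorgans (cM), times in units of
2N generations of the reference (autosomal) population, mutation as the
per-site population rate θ = 4Nμ.

## Y-SNP segregation and wild screening

A site is called a Y-SNP when the father is heterozygous for allele *a*,
the mother carries no copy of *a*, every genotyped son carries *a* and no
genotyped daughter does (`segregation.call_cross_ysnps`). "Carries" means
≥ 1 copy: RNA-seq allele dropout makes heterozygous/homozygous calls
unreliable, so a son homozygous for the Y allele still counts as a
carrier and is logged as a soft violation. Sites with a missing parental
genotype are uncallable; progeny with missing calls are dropped per site,
with configurable minimum counts (default 10 sons / 10 daughters — a
conservative half of each progeny class).

Wild-sample male specificity is evaluated per species at two stringency
levels: the Y allele in ≥ k wild males (default k = 2) and in all
genotyped wild males, in both cases with zero carrier females; any
female carrier overrides (`present_in_females`). The two-individual
third species is classified by (present in the male, absent in the
female) only. Y-SNPs seen in wild females despite clean cross
segregation are reported in their own category rather than adjudicated —
they may be mis-calls or genuine rare X–Y recombination.

## Degeneracy and site selection

Synonymous statistics use third codon positions that are 4-fold
degenerate given the *reference* codon under the standard genetic code.
A 4-fold position enters the analysis only when the first two positions
of its codon are monomorphic and non-missing across the analysed
haplotypes; alternative-allele amino-acid changes at positions 1–2
therefore exclude the codon rather than re-classify it. Monomorphic
4-fold positions count toward the per-gene denominator L4. Internal stop
codons trigger a warning and truncate the classified CDS.

## Summary statistics

* π: per-site unbiased heterozygosity n/(n−1)(1 − Σp²) summed over sites
  and divided by L4; computed from allele frequencies, which equals the
  mean pairwise difference on fully called data. Sites with fewer than 4
  called alleles (configurable) are dropped.
* Tajima's D: standard constants for the number of haplotypes; null when
  no site segregates.
* Kelly's ZnS: mean r² over pairs of segregating biallelic sites,
  computed on haplotypes jointly called at both sites; requires phase.
* Kst\*: with pairwise distances d and K\*_g the mean ln(1+d) over
  within-group pairs, pair-count weights make K\*_S the pooled
  within-group mean; Kst\* = 1 − K\*_S/K\*_T. The permutation test
  permutes *individuals* (a diploid's two haplotypes move together),
  because allele-level permutation would break within-individual
  correlation. When the number of distinct label arrangements is at most
  the permutation budget the full enumeration is used and the p-value is
  exact; otherwise p = (1 + #{K\*perm ≥ K\*obs})/(1 + n_perm).
* Fst: Hudson's within/between estimator, 1 − mean(π_w)/π_b, on pairwise
  difference counts (the site denominator cancels).

Heterozygote phase is unobservable in real data; Kst\*/ZnS on genotype
input use y-aware pseudo-phasing (Y alleles forced onto the Y-labelled
copy of males, remaining heterozygous sites split by a seeded draw) and
are documented approximations. Simulated data carries true phase.

## Gametolog consensus and divergence

Fragments (read pairs reduced to the segregating sites they cover) are
labelled Y if they carry the Y allele at ≥ 1 Y-SNP and the X allele at
none, X in the mirror case; fragments carrying both conflict and are
discarded with a count. Per-label consensus takes the majority allele
per site over the species-A male fragments (father + 7 wild males), with
ties or depth < min_depth giving N. Raising min_depth can only convert
calls to N, never flip them, on error-free input.

Silent divergence is the Jukes–Cantor-corrected mismatch fraction,
d = −(3/4)ln(1 − 4p/3), over comparable 4-fold positions (both sequences
non-N at the position and its codon partners, partners equal between the
sequences); null below 10 comparable sites (configurable). JC is the
simplest correction and adequate here because the divergences involved
are ≤ ~0.1, where model choice is negligible. Outgroup divergence
compares the ingroup major-allele consensus with the outgroup sample's
consensus at the same sites. An all-silent-positions option (vs 4-fold
only) is available through the degeneracy mask.

## HKA and ML-HKA

Per locus i: S_i segregating 4-fold sites among n_i sampled alleles over
L_i sites, D_i mismatches to the outgroup at the same sites, ploidy
factor x_i (1 autosomal/pseudoautosomal, 0.75 X-linked — PAR loci are
treated as autosomal because they recombine in both sexes). Moments:

    E[S_i] = x_i θ_i a_{n_i},  Var[S_i] = E[S_i] + (x_i θ_i)² b_{n_i}
    E[D_i] = θ_i (τ + x_i),    Var[D_i] = E[D_i] + θ_i²

The classical test estimates (θ_1..θ_L, τ) from the moment equations —
total S, total D, and the per-locus totals S_i + D_i for all but the
last locus match their expectations; τ is the root of the (monotone)
total-divergence equation — and refers X² to chi-square with L − 1
degrees of freedom. Direct minimisation of X² was evaluated and
rejected: because the variance terms grow with θ, the minimiser inflates
θ to deflate the standardised residuals, and the resulting test is far
too conservative (type-I error ≪ 1%); the moment-equation version is
near-nominal. Degenerate systems (no valid root, non-positive θ) fall
back to numerical minimisation rather than failing.

ML-HKA uses independent Poisson likelihoods with a per-locus selection
parameter k scaling both polymorphism and the ancestral-polymorphism
component of divergence: S_i ~ Poisson(k_i x_i θ_i a), D_i ~
Poisson(θ_i(τ + k_i x_i)); k ≡ 1 for non-selected loci. θ_i has the
closed-form profile MLE (S_i + D_i)/(k_i x_i a + τ + k_i x_i), so only
(τ, k_selected) are optimised (log-parameterised Nelder–Mead, 10 seeded
restarts). The deliverable is the MLE and likelihood-ratio test (df =
#selected), not posterior samples. Per-gene runs free one k per run
against a fixed reference set (the ancient-stratum X-linked genes, or an
autosomal panel); raw p-values are reported with a clearly-labelled
Benjamini–Hochberg column added.

## Boundary changepoint

The per-species, per-stringency indicator is "gene has ≥ 1 male-specific
SNP". The boundary is the cut maximising the two-segment Bernoulli
likelihood with the distal rate constrained below the proximal rate; the
LRT against a single rate measures support, and a 1000-replicate
bootstrap (genes resampled within segments) gives a CI — the package's
representation of the "fuzzy boundary" idea. Only gene order matters.
Both stringency levels are run; the lenient boundary is reported with
the strict one recorded. Region labels: left = distal to species A's
boundary, mid = between the two species' boundaries (sex-linked in A
only), right = proximal to species B's boundary; A's boundary proximal
to B's violates the nested-expansion assumption and is an error.

## Expression

FPKM = counts · 10⁹ / (effective length · total mapped reads). Per-gene
bias is log₂(median female FPKM) − log₂(median male FPKM) over wild
accessions by default (configurable sample mask); a zero median adds a
flagged pseudocount of 0.01. Region contrasts are Welch t-tests on
per-gene biases.

## The synthetic-data generator

Each gene draws haplotypes from a structured Kingman coalescent with
infinite-sites mutation (biallelic SNPs by construction, no intragenic
recombination). Founder chromosomes: cross father (X, Y) and mother, 7
wild males and 7 wild females for each sister species, one male and one
female of the third species, one diploid outgroup — 66 lineages, 85
samples once the 52 progeny are produced by meiosis. Pools and relative
sizes: X pools 0.75, Y pools 0.10 (the Y's drastically reduced effective
size), panmictic pools 1.0; the left-region diversity multiplier k
(balancing-selection proxy, default 1) scales pool sizes, not split
times, so it inflates polymorphism without inflating divergence — the
signature the HKA tests are meant to detect.

Event times (defaults, 2N units): mid-stratum arrest t_mid = 0.30
(species A only), species A–B split 1.0, third-species split 1.4,
ancient-stratum arrest t_right = 1.62, outgroup split 6.5; θ = 0.015 per
site over 1200-bp all-CDS genes. The arrest ages and outgroup split were
calibrated once, by simulation, so that the pipeline's consensus-based
silent divergence averages ≈ 0.016 (young stratum) and ≈ 0.049 (ancient
stratum) with outgroup divergence ≈ 0.10 and indistinguishable across
regimes — the magnitudes the analysis is designed around. t_mid trades
off two targets that pull in opposite directions — the young stratum's
dS and the density of male-specific SNPs on the young Y (the boundary
signal) — and is set at the value that keeps the young-stratum dS within
~15% of target while nearly every mid gene carries at least one
male-specific SNP, matching the qualitative pattern the analysis
presumes; both realised quantities are measured, not assumed, by the
acceptance script.

The cross places Haldane crossovers along the map per meiosis. Male
meioses recombine only distal to species A's suppression boundary, and
PAR distances are expanded ×7 relative to the sex-averaged map: male
crossovers are confined to the PAR (the obligate X–Y chiasma), so the
male PAR map is several-fold longer than the sex-averaged one — without
this, a 52-meiosis cross would show spurious Y-like segregation at many
pseudoautosomal genes, which contradicts how such crosses behave.
Sons receive the paternal gamete carrying the sex-determining proximal
end. Genotypes are emitted unphased; the true phase is retained
separately.

Fragments tile runs of 3 adjacent segregating sites at coverage 10 per
haplotype, error-free by default with an optional flat per-allele error
rate; they are emitted for species-A males, the inputs of the X/Y
consensus reconstruction. Expression counts are negative-binomial
(dispersion 0.3) with log-normal library sizes; per-sample totals model
the whole transcriptome (library factor times a sex-independent
constant) rather than the analysed panel's column sums, because the
panel's sex-linked composition must not leak into the FPKM denominator.
Male expression at a
gene sex-linked in the sample's species is (1 + δ)/2 of the female mean,
δ = 0.75 (young stratum) and 0.5 (ancient stratum, a ~1.3-fold female
excess in FPKM and ~2-fold on the Y allele itself).

What the generator does **not** emulate: genotyping error and allele
dropout, coverage variation across genes and samples, intragenic
recombination, gene flow between the sister species (a symmetric-rate
option exists but is off by default), selection acting forward in time,
and mapping artefacts. Passing tests therefore demonstrate correctness
of the inference machinery under the study's idealised generative
assumptions, not robustness to real RNA-seq noise.

## Problem sizes and determinism

Statistical checks use scaled simulation designs chosen as the package's
own defaults: 200 replicate datasets for boundary-recovery and Y-SNP
fidelity, 30 for divergence recovery, 200 neutral genes (n = 20,
θ = 0.01/site) for estimator calibration, 200 null datasets and 100
k = 4 datasets (5 resp. 20 + 1 loci, θ = 10 per locus, τ = 7 — the
divergence-to-diversity ratio of the study system) for the HKA operating
characteristics. The null HKA counts are drawn hierarchically — Poisson
given a coalescent tree length, and given τ plus an exponential
ancestral coalescence time — exactly matching the variance structure the
test assumes. All randomness flows from one master seed; reruns are
byte-identical, which the test suite asserts on full pipeline output.

## Known limitations

* The changepoint model assumes a single clean transition per species;
  a genuinely gradual suppression gradient would be summarised by the
  bootstrap CI rather than modelled.
* ML-HKA's k̂ is a ratio-type estimator and noisy when divergence is
  shallow; with deep outgroups (τ ≈ 7) its median is close to truth but
  individual estimates are heavy-tailed.
* Consensus-based dS slightly exceeds the stem-age expectation because
  within-pool lineage sorting contributes majority differences; the
  calibration absorbs this.
* Kst\*/ZnS on real (pseudo-phased) data inherit phasing error at
  non-Y-SNP heterozygous sites; the sex-contrast Kst\* is dominated by
  Y-allele differentiation, which y-aware phasing assigns correctly.
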