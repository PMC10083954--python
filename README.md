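# parshift

Locating the pseudoautosomal-region (PAR) boundary on plant sex
chromosomes from transcriptome SNPs — and detecting when the
non-recombining Y region (NRY) has recently expanded.

## The problem

In dioecious plants such as white campion (*Silene latifolia*) and its
sister species, X and Y chromosomes still recombine in males inside the
PAR; outside it the Y is male-limited and slowly degenerates. The map
position separating the two — the PAR boundary — can shift, adding a new
"evolutionary stratum" to the NRY. `parshift` implements the full
analysis that localises the boundary in each species and characterises
the newly sex-linked stratum:

1. **Y-SNP segregation** — in a genetic cross (father, mother, 20 sons,
   32 daughters), an allele transmitted from a heterozygous father to
   *every* son and *no* daughter marks a Y-linked site.
2. **Wild-sample screening** — a cross cannot see rare recombination, so
   each candidate is re-screened in unrelated wild accessions: carried by
   ≥ 2 (lenient) or all 7 (strict) wild males and no wild females.
3. **Boundary inference** — per-gene indicators (≥ 1 male-specific SNP),
   ordered along the genetic map, are cut by a two-segment Bernoulli
   changepoint with a likelihood-ratio statistic and bootstrap CI; the
   region between the two species' boundaries is the young stratum.
4. **Population genetics at 4-fold degenerate sites** — π (Nei's
   unbiased heterozygosity), Tajima's *D*, Kelly's *Z*nS, the sequence
   differentiation statistic *K*st\* (1 − mean within-group / total
   ln(1+d) pairwise distance) with an individual-level permutation test,
   and Hudson's *F*st.
5. **Gametolog divergence** — read fragments are tagged X/Y by the
   Y-SNPs they carry, per-label majority consensi are built, and
   Jukes–Cantor silent divergence dS(X,Y) dates each stratum.
6. **HKA / ML-HKA selection tests** — polymorphism/divergence ratios
   across loci, with ploidy factor x (0.75 for X-linked loci) and, in the
   ML variant, a per-locus selection parameter k fitted by profile
   likelihood (k > 1 ⇒ balancing selection), tested by LRT.
7. **Expression bias** — per-gene log₂(median female FPKM) −
   log₂(median male FPKM), with Welch t-tests between regions.

A first-class structured-coalescent simulator (`parshift.simulate`)
generates complete datasets with the study's design — species × X/Y
lineage pools merging backwards at stratum ages and species splits, a
pedigree cross with male recombination suppressed proximal to the
boundary, read fragments and negative-binomial counts — plus a ground
truth record, so every stage can be validated against known answers.

## A worked example

```python
from parshift import SimulationConfig, simulate_dataset
from parshift.pipeline import RunConfig, run_pipeline

dataset = simulate_dataset(SimulationConfig(), seed=42)
result = run_pipeline(dataset, RunConfig(seed=7, n_perm=200, n_boot=200))

a, b = result.regions.boundary_a, result.regions.boundary_b
print(a.cut, b.cut)                      # 20 36  — both boundaries exact
print(result.hka_concat[["x2", "p"]])    # x2=0.001, p=0.975 (no PAR excess at k=1)
```

With the default configuration (57 genes: 20 pseudoautosomal, 16 recently
sex-linked in species A only, 21 anciently sex-linked) the inferred cuts
20 and 36 match the simulated truth, meaning every gene is assigned the
correct left/mid/right region. Per-gene statistics show the expected
sex-chromosome signature — in the ancient stratum male π ≈ 0.023 versus
female π ≈ 0.013, because X–Y divergence segregates in males — and the
divergence stage recovers mean dS(X,Y) ≈ 0.014 for the young stratum
versus ≈ 0.046 for the ancient one in this replicate (long-run means
≈ 0.017 and ≈ 0.051). The `examples/` directory walks
through each capability as a short narrative script; `parshift --help`
exposes the same stages as a thin command line
(`simulate`, `report`, `hka`, `mlhka`).

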