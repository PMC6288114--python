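# Methods

## The window ancestry model

The per-SNP statistic contrasts an individual's diploid call
(`q ∈ {0, 0.5, 1}`) with one reference population's alternate-allele
frequency `p` as `b = (Ht − Hs)/Ht`, with
`Hs = p(1−p) + q(1−q)` and `Ht = 2 p̄ (1−p̄)`, `p̄ = (p+q)/2`. Because
`Ht − Hs = (p−q)²/2`, the statistic is symmetric in its arguments,
non-negative, and equals 1 exactly at a fixed difference. It treats the
individual as a "population" of two chromosomes, so even an animal drawn
from the reference itself has positive expected `b` (heterozygosity is
bounded at 0.5 on the individual side); the statistic is therefore only
meaningful *comparatively*, between two reference panels, which is how
the pipeline uses it throughout.

SNPs where `Ht = 0` (individual and reference agree monomorphically)
carry no information and are excluded before window averaging, never
silently propagated as NaN. Missing genotypes drop the SNP for that
animal only.

Windows are fixed, adjacent, non-overlapping, anchored at position 1 of
each chromosome: window `i` covers `[i·W+1, (i+1)·W]` 1-based with
`W = 250,000` by default. A window is callable against a reference when
it holds at least `min_snps` (default 10) defined SNPs. Genome-wide
("global") values pool per-SNP values over all defined SNPs rather than
averaging window means, so SNP-dense windows weigh more; both the pooled
and the per-animal-mean cohort summaries are emitted, labelled.

Window origin is decided by which reference side has the lower window
average; exact ties are a no-call in segment classification. In the
*composition fraction* (share of taurine-derived windows per animal),
ties are instead split deterministically by window-index parity — with
identical inputs on both sides every window ties, and the parity rule
lands the degenerate case near 50/50 instead of 0 or 100%.

The per-window contrast reported for ranking and heatmaps is the signed
symmetric percent difference `100·(b_ind − b_tau)/((b_ind + b_tau)/2)`;
positive values mark taurine-like windows. Top-window selection takes
`⌈fraction · callable⌉` windows (default 5%) from the requested tail,
with ties broken by (chromosome, window index) so the selection is
order-independent.

## Segments and length spectra

Maximal runs of same-origin windows form segments; no-call windows and
chromosome boundaries break runs (a no-call is absence of evidence, not
continuation), as do gaps in the window index (SNP deserts). Length
spectra are pooled over animals (per-animal tables are also available).
The comparison against the neutral simulation reports each dataset's
maximum segment length and an exceedance fraction — the share of
simulated segments at least as long as the longest observed one — rather
than a formal test, since the argument is "no neutral segment this long
was ever produced".

## The breed-formation simulator

`breed_sim` is a self-contained forward Wright–Fisher model of the
breed's history: an ancestral diploid population evolves to
mutation–drift equilibrium, splits into taurine and indicine populations
that diverge in isolation, and an admixed population is formed and
random-mates for a fixed number of generations. No selection acts
anywhere. Full-scale defaults: ancestral N = 10,000 diploids, 100,000
generations of burn-in, 10,000 of divergence, 30 of admixture, 1,000
admixed animals; genomes are 5 independent loci of 10 Mb with mutation
and recombination rates of 0.01 per locus per generation (at most one
crossover per locus per meiosis, free recombination between loci;
infinite-sites mutation, no back-mutation). The locus *count* is a
desk-scale choice (50 Mb of genome keeps well over 10,000 segregating
sites in rescaled runs); locus length and rates are model constants.

Two phases use different resolutions:

- **Burn-in and divergence** evolve per-site allele counts
  (binomial resampling of 2N chromosomes per generation, Poisson influx
  of new singleton sites, pruning of sites lost or fixed everywhere).
  Under neutrality the marginal frequency trajectory of each site is
  exactly Wright–Fisher; what this resolution forgoes is within-locus
  linkage in the founder populations, which none of the downstream
  quantities (FST, admixture tracts) depend on.
- **Admixture** is individual-based: haplotypes carry alleles at every
  site plus ancestry tracts, transmitted through explicit meioses.
  Founder allele frequencies are frozen during the 30 admixture
  generations and mutation is skipped there — both effects are of order
  30/2N and negligible. Two designs are available: a literal
  cross-breeding event (F1 hybrids, then random mating; the default) and
  a grading-up design (F1, then `n_backcross_gens` generations of
  backcrossing to indicine sires, then random mating). Grading-up with
  2 backcrosses (expected 12.5% taurine, the integer design closest to
  the breed's ~10% taurine makeup) is what reproduces the reported
  admixed-vs-taurine differentiation of ~0.25: a 50/50 hybrid
  mathematically caps FST(admixed, taurine) near one quarter of the
  founder FST, far below the reported value.

**Rescaling.** `scale_factor s` divides N and the burn-in/divergence
generation counts and multiplies per-generation rates by `s`, preserving
drift time t/2N (validated to 1%) and population-scaled rates. The
admixture phase is never rescaled — its 30 generations and census of
1,000 are simulated literally. The acceptance run uses `s = 20`
(N = 500, divergence 500 generations, t/2N = 0.5): ten replicates finish
in about two minutes on one CPU and carry ~28,000 segregating sites.

`init_sites_per_locus` seeds standing variation from the neutral 1/x
site-frequency spectrum, which makes mutation-free (pure drift) runs
possible; with drift only, founder FST matches the closed form
1 − e^(−t/2N) (≈ 0.39 at t/2N = 0.5), while with mutation active the
same depth gives ≈ 0.33 because new mutations add weakly differentiated
sites. Both regimes are tested at their own expectations.

**FST** is the two-population Weir & Cockerham (1984) estimator computed
from genotype counts with the standard sample-size corrections; the mean
over sites is the ratio of summed variance components (the "weighted"
estimate of vcftools). Sites with fewer than two called genotypes in
either sample, or with a vanishing denominator, are skipped.
`tune_divergence` bisects the divergence generations against a target
mean FST over replicate simulations.

## Synthetic data

The generator provides the study conditions for every test:

- **Founder panels**: ancestral frequencies uniform on [0.05, 0.95]
  (avoiding near-monomorphic degenerate sites), daughters drawn from the
  Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F) with F the target
  divergence; F = 0 bypasses the Beta draw exactly. Calibration: the
  empirical Weir–Cockerham FST of large samples recovers F within 0.03
  at 10,000 sites.
- **Mosaic cohorts**: each haplotype tiles the chromosome with
  exponential-length tracts whose origins are i.i.d. taurine with the
  target probability (Markovian ancestry switching); alleles are
  Bernoulli draws from the tract origin's panel, genotypes are haplotype
  sums, and the tract truth is returned for recovery scoring. The
  default recovery conditions — F = 0.25, ~75 SNPs per 250 kb window,
  10% taurine, 2 Mb mean tracts — give ≥ 90% window classification
  accuracy against truth.
- **Depth profiles**: per-window counts are Poisson with mean
  depth × window × copy factor, the factor being 1 + (extra copies
  carried)/2 over a duplication footprint (homozygous single extra copy
  ⇒ 2.0, heterozygous ⇒ 1.5) and 1 − (deleted haplotype fraction) over
  a deletion, pro-rated by partial window overlap. Aligned-read
  intervals are simulated at uniform coverage; reads crossing a deleted
  sequence are split at the deletion (emulating clipped alignments), so
  carriers have no spanning reads.

What the generator does *not* emulate: linkage disequilibrium within
founder panels, mapping artefacts (repeats, CNV-driven mismapping), GC
or mappability bias in coverage, genotyping error, or related animals.
Passing recovery tests therefore demonstrate the statistical machinery
under clean conditions, not robustness to those real-data artefacts.

## Polled-locus coverage scan

Read counts in 50 bp windows are standardised to SD-from-mean units
within each group's profile across the scanned region (the alternative —
per-window SDs across animals — would need per-animal profiles; the
group-level curve is what the scan compares). Duplications are called as
maximal runs of at least `min_windows` (default 4) consecutive windows
where carrier z minus reference z is ≥ `z_threshold` (default 2.0); the
defaults make a 212 bp (≥ 4-window) duplication detectable while single
noisy windows are not. Fold change over a run is computed after
normalising each profile by its own regional mean, so cohorts sequenced
at different depths (the study range is 10–30×) do not mimic CNVs.
Deletion evidence counts reads fully spanning the short target interval
per animal; at 12.5× with 100 bp reads over a 16 bp target the
non-carrier expectation is depth·(L−t+1)/L ≈ 10.6 reads, and homozygous
carriers show zero. Candidate intervals (the Celtic 212 bp replacement
at chr1:1,706,051–1,706,060 and the Friesian 1.91–1.99 Mb duplication)
are configuration, not hard-coded logic.

## Fixed alleles and enrichment statistics

A fixed alternate site has every called animal homozygous-alternate
(strict mode also forbids missing calls) and is absent from the
comparison panel. Class summaries report counts, percent of total
(3-decimal convention) and the signed *symmetric* percent difference
`100·(a−b)/((a+b)/2)` against the genome-wide class percentage — the
formula that reproduces the published table's difference column from its
own percentages. The chi-square test compares fixed-class counts with
expectations proportional to genome-wide counts, pooling classes with
expected counts below 5 into "other" (the standard validity rule);
its type-I error is calibrated at the nominal 5% by multinomial
simulation. The keyword permutation null draws same-size gene sets
i.i.d. from the universe (ignoring genomic clustering of genes, as the
procedure it mirrors does), scores a keyword once per permutation in
which any sampled gene carries it, and reports add-one empirical
p-values (count+1)/(n_perm+1) so finite permutation counts never produce
p = 0.

## Numerical and interface conventions

Coordinates are 1-based inclusive everywhere internally (VCF
convention); BED exports convert to 0-based half-open. Genotypes are
int8 codes 0/1/2 with −1 for missing. Multi-allelic and non-SNP VCF
records are skipped with a logged count; allele-mismatched sites in
coordinate joins are dropped and logged, never strand- or allele-flipped.
Chromosome names are taken verbatim. All generators and simulations are
deterministic given their seed.

## Known limitations

- The window classifier is threshold-based; heterozygous-ancestry
  windows (one haplotype from each origin) sit near the decision
  boundary and classify noisily. This is intrinsic to the method and is
  why called single-window segments dominate neutral simulations.
- The simulator's admixture census and design are simplified (no
  pedigree structure, no sex chromosomes, discrete generations).
- Diploid male X dosage is not modelled; sex chromosomes are processed
  like autosomes and flagged upstream.
- The chi-square enrichment machinery is validated by construction and
  calibration, but the full genome-wide class count table needed to
  reproduce the published statistic is not part of the printed record.
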