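# Methods

`equimhc` analyses diploid microsatellite genotypes from pedigreed horse
populations typed at a panel of linked MHC markers. Alleles are PCR fragment
lengths in bp; allele identity is length identity, with no sequence-level
resolution. All statistics treat a locus with either allele missing as
wholly missing and drop individuals per locus (pairwise deletion), so every
locus carries its own sample size, as in Cervus-style outputs.

## Locus panel and coordinates

The default panel holds the 11 intra-MHC microsatellites on equine
chromosome 20 in chromosome map order: three class I markers, two class III
markers, six class II markers. No physical positions are used anywhere:
breakpoints are reported as intervals named by the flanking locus pair.
Published maps do not fully constrain the internal order of the class I
markers, so panels are constructable in any order (`map_index` decides).
`repeat_unit` (default 2 bp, dinucleotide) defines the stepwise-mutation
lattice; `size_range` bounds the simulator's allele lattices.

## Diversity statistics

* **He** is unbiased gene diversity, `(2n/(2n-1)) (1 - sum p_a^2)` with `2n`
  the gene count. **Ho** is the fraction of typed individuals with two
  distinct alleles.
* **PIC** is the Botstein form `1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2`;
  it never exceeds He.
* **Fis** defaults to the ratio form `1 - Ho/He`, which is how the published
  per-locus tables this package mirrors behave numerically; the
  Weir–Cockerham within-sample f is available (`fis_weir_cockerham`) and is
  reported alongside in the stats table.
* **Allelic richness** is hypergeometric rarefaction,
  `AR = sum_a [1 - C(N - N_a, g) / C(N, g)]`. The default rarefaction size
  `g` is the smallest per-locus gene count among the populations being
  compared, which makes the smallest population's AR its raw allele count.
* **Null-allele frequency** is the Chakraborty estimator
  `(He - Ho)/(He + Ho)`; negative values flag heterozygote excess. The
  maximum-likelihood estimator used by some pedigree software is not
  implemented; where the two disagree it is typically in the second decimal.
* **HWE** is the conditional exact probability test: conditioned on allele
  counts, `P(table) = n! 2^h prod n_a! / (prod n_gg! (2n)!)`; the p-value is
  the mass of tables no more probable than the observed one. Tables spaces
  up to 1e5 tables are fully enumerated; beyond that a Monte-Carlo version
  shuffles the gene vector (default 1e5 shuffles, add-one correction).
  Ties in probability are accepted within 1e-9 in log space. Monomorphic
  loci return p = 1 with a "not testable" flag rather than NA so tabulations
  keep all rows.
* **LD** between locus pairs is the genotypic contingency-table G statistic
  with a permutation null (default 999 permutations of one locus's
  genotypes; add-one correction).
* The **chi-square homogeneity** test compares per-population gene counts;
  Bonferroni correction multiplies by the number of loci tested in the run
  (11 for the default panel), applied per test family.
* **ΔK** for choosing the number of clusters from external admixture runs is
  the absolute second difference of mean log-likelihood over K divided by
  the replicate standard deviation; zero deviation yields an infinite ΔK,
  which is surfaced rather than masked.

## Differentiation

Nei's genetic identity uses the unbiased within-population homozygosities
`(2n J - 1)/(2n - 1)`, J values averaged over loci, `I = Jxy / sqrt(Jx Jy)`
and `D = -ln I` (reported as infinity when no alleles are shared).

AMOVA is the three-level hierarchical partition (among populations, among
individuals within populations, within individuals). The distance metric is
the per-locus allele mismatch count — no repeat-size weighting, because the
analyses this package reproduces used identity-in-state, not RST — summed
over loci and rescaled by panel size over shared typed loci. Sums of
squares are computed at the gamete level, which requires no phasing: within-
individual distance is the heterozygous-locus count, and between-individual
terms sum the four allele cross-pairs. Variance components come from
equating mean squares with the standard unequal-size coefficient; negative
components are reported raw and truncated to zero for the percentage
breakdown (a flag lists truncated levels). Φ-statistics are ratios of the
truncated components; significance is by permuting individuals among groups
(default 999, add-one). Clonal datasets (total variance 0) return a
`degenerate` flag with undefined percentages.

Pairwise Fst defaults to Φ-PT from the same three-level AMOVA restricted to
the two populations, so the pairwise value and the two-population AMOVA are
identical by construction; Weir–Cockerham θ is available behind
`estimator="wc"`. Cluster-regrouped AMOVA re-runs the identical computation
with externally supplied assignments (e.g. from a Bayesian admixture run;
the admixture inference itself is out of scope, only its output is
post-processed).

## Trio phasing

Phasing is constraint-based, algorithmizing manual trio comparison; there
is no statistical or LD-based phasing and no imputation. Evidence enters in
three forms:

1. **Mendelian forcing** within a trio/pair, locus by locus: assignments
   are resolved when exactly one parental-origin labelling is consistent,
   ambiguous when both are, conflicts when neither is.
2. **Complement closure**: a parent's two haplotype alleles at a locus are
   exactly its genotype pair, so each established allele determines its
   homolog.
3. **Haplotype context**: a parent accumulates phase from the haplotypes it
   transmitted; ambiguous offspring loci are resolved only when exactly one
   assignment matches an established parental haplotype.

Two design choices go beyond single-locus forcing, and both exist because
rare meiotic events otherwise corrupt the reconstruction:

* **Consensus, not first observation.** A parent's haplotype allele is the
  consensus of the transmissions classified to that haplotype, and the
  anchor haplotype is the transmission most consistent with its siblings.
  With first-observation-wins, a single recombinant or mutated transmission
  anchors a mosaic as the parent's "haplotype", which both hides the true
  event and manufactures spurious events in every sibling.
* **Context correction.** A repeat-unit mutation whose new allele happens to
  match the *other* parent's genotype produces a Mendelian-forced but wrong
  assignment (roughly half of simulated stepwise mutations under realistic
  allele counts). A correction pass re-compares the two possible
  attributions by total context cost — exact haplotype match 0, conversion
  or stepwise mutation 1, inexplicable infinity — and re-attributes only
  when the alternative is strictly cheaper, or when an otherwise
  unattributable conflict has a unique cheapest reading. Tied attributions
  of a conflict are resolved deterministically; the event count is the same
  either way, only the parent of origin is uncertain.

Unresolvable loci stay unknown. Conflict loci are excluded from haplotypes
and handed to event calling with their attributed alleles. Iteration order
is sorted by id, so results are independent of input row order. Haplotype
identity in the inventory requires all panel loci resolved; partially
resolved haplotypes are tallied separately, never counted as distinct.

## Event calling

Each resolvable transmission (parent fully phased, transmitted haplotype
resolved at ≥ 2 loci) is explained as a minimum-cost combination of
crossovers, gene-conversion tracts and stepwise indels. The cost ordering
is lexicographic: fewest event records (one recombination record covers all
its breakpoints), then fewest breakpoints, then fewest point events. This
reproduces the intended ranking none < conversion = indel < 1 breakpoint <
2 breakpoints < conversion+indel, which no positively weighted scalar can
express.

Conventions, fixed identically in the implementation and in the exhaustive
test oracle:

* Only loci where the parental haplotypes differ ("informative") carry
  mosaic signal; breakpoints are localized to the interval between flanking
  informative loci, and uninformative loci can only widen an interval.
* A conversion tract spans at most two loci and requires a *demonstrated*
  same-haplotype flank on both sides — an informative, cleanly matched
  locus. An uninformative or mutated flank demonstrates nothing, so
  effectively-terminal single-locus switches are recombination.
* A single-locus switch at a terminal panel locus ties between recombination
  and conversion; recombination wins by convention unless the offspring
  demonstrably carries both of that parent's alleles while the other parent
  is excluded (the non-reciprocal duplication pattern), which is conversion.
  All ties are recorded in the output.
* An indel is a single-locus allele matching neither parental allele at an
  offset of 1–3 repeat units from a parental allele; larger or off-lattice
  offsets mark the transmission unexplained. Unexplained and skipped
  transmissions are counted, never dropped.
* Search budget: up to 3 breakpoints plus one point event (conversion
  tracts are segment reinterpretations, not point events).

Per-meiosis frequencies divide transmission-level event counts by the
number of parent-offspring pairs (two per full trio, one per single-parent
pair). The new-haplotype ratio counts distinct fully resolved offspring
haplotypes absent from the parental generation's haplotype pool, over the
same denominator. Parent sex is carried on every event, so statements about
paternal or maternal origin are outputs, not assumptions.

## Synthetic data generator

The simulator emulates the study design the statistics are built for: three
populations of roughly 100/32/38 horses (49+8, 16+4, 19+4 founders with
43/12/15 trio offspring), 11 loci with per-locus founder allele counts
matching the observed 5–14 range, and rare planted meiotic events. Default
rates: crossover 0.007 per interval per meiosis (≈ 7% of meioses carry a
crossover on the 10-interval panel), conversion 0.02 per meiosis with a 1–2
locus internal tract, indel 0.0018 per locus per meiosis (≈ 27 events per
140 meioses across 11 loci), each chosen to match the event counts the
per-meiosis frequencies are computed from. Founders draw two haplotypes
uniformly from a per-population pool (random union of gametes, hence exact
HWE at the haplotype level); pool size defaults to 1.6 × founder count,
giving within-population haplotype diversity of the order seen in the study
populations. Pools are disjoint across populations except for a configured
shared fraction (0.10 between the two related populations), which is the
differentiation dial. Allele sizes sit on the repeat-unit lattice inside
each locus's size range, so planted indels can — but need not — recreate an
existing allele, exactly the collision case the phasing correction pass
exists for.

Randomness is a single root seed with counter-based substreams per meiosis
(keyed by population, offspring and parent side), so adding offspring never
perturbs earlier draws and a given seed is byte-reproducible. The truth log
stores founder phases and every planted event; replaying it reconstructs
every offspring genotype exactly, and each meiosis carries an `effectual`
flag — whether the transmitted haplotype differs from both parental
haplotypes. Recovery tests compare called events against effectual planted
events, because a conversion copying an allele onto an identical allele or
a crossover inside a homozygous stretch leaves no molecular trace and is
undetectable by any method.

What the generator does **not** model: crossover interference, mutation
models beyond ±1 repeat unit, genotyping error and allelic dropout,
multi-generation pedigrees, population growth or selection, and null
alleles. Passing recovery tests therefore demonstrate correctness of the
inference machinery under clean typing, not robustness to laboratory
artefacts.

## Problem sizes used in the test suite

The suite phases and calls events on 1000 simulated trios (2000 meioses)
for rate recovery, 500 trios for zero-event phasing recovery, study-sized
datasets (170 individuals) for the integration checks, 1000 random ≤6-locus
cases for the exhaustive-search equivalence, and every 2-allele genotype
table up to n = 10 for the exact-test agreement, with 2000 Monte-Carlo
shuffles per table. These sizes give the property tests their stated
binomial tolerances while keeping the suite fast.

## Known limitations

* Phasing detects events only on transmissions whose parent can be phased
  independently; a parent with a single offspring contributes Mendelian
  conflicts (indels) but not crossover or conversion calls.
* Two identical recombinant transmissions from one parent can outvote a
  single pure transmission during anchoring; parsimony then prefers the
  wrong phase and misattributes the events. This is an identifiability
  limit of parsimony, not an implementation defect; it is rare at realistic
  rates and is why recovery is asserted within binomial confidence bands
  rather than exactly.
* Conversion versus a colliding indel at a single locus can be inherently
  indistinguishable; the convention (conversion when the allele equals the
  homolog's) is applied consistently.
* Fis and the null-allele estimator are ratio statistics of He and Ho and
  inherit their small-sample noise; no jackknife confidence intervals are
  provided.
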