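# equimhc

Diversity and haplotype analysis of equine MHC microsatellites from
pedigreed populations.

The major histocompatibility complex (MHC) is the most polymorphic region
of the vertebrate genome, and in horses it is routinely typed with a panel
of 11 intra-MHC microsatellites spanning the class I, III and II subregions
of chromosome 20. Because the markers are tightly linked, family material
makes whole MHC *haplotypes* observable: comparing the genotypes of dams,
sires and offspring phases each chromosome copy, and any offspring
haplotype that matches neither parental haplotype exposes a meiotic event —
a crossover, a gene-conversion tract, or a repeat-unit insertion/deletion.
`equimhc` is for population geneticists who have such genotype + pedigree
tables and want, from one package:

* **trio phasing** — constraint-based reconstruction of maternal/paternal
  haplotypes with no statistical imputation, plus the per-population
  haplotype inventory and cross-population sharing;
* **meiotic event calling** — minimum-cost classification of each
  transmission into crossover / conversion / insertion / deletion with
  breakpoint intervals on the locus map, per-meiosis frequencies
  (denominator = parent–offspring pairs, two per full trio) and the
  new-haplotype ratio;
* **the diversity panel** — Ho, unbiased He = (2n/(2n−1))(1 − Σp²), PIC,
  Fis = 1 − Ho/He (Weir–Cockerham f optional), rarefied allelic richness,
  effective/private alleles, the Chakraborty null-allele estimator
  (He−Ho)/(He+Ho), the conditional exact HWE test (full enumeration or
  Monte-Carlo), genotypic LD G-tests, and chi-square allele-frequency
  homogeneity with Bonferroni correction;
* **differentiation** — unbiased Nei identity/distance (D = −ln I),
  three-level codominant AMOVA with Φ-statistics and permutation tests,
  pairwise Fst (Φ-PT, identical to the two-population AMOVA by
  construction), cluster-regrouped AMOVA for external admixture
  assignments, and Evanno ΔK for choosing the number of clusters;
* **a forward pedigree simulator** that emulates the three-population study
  design (100/32/38 horses, 5–14 alleles per locus, family trios) with
  planted meiotic events and an exact, replayable truth log.

## Worked example

```python
import equimhc as eq

# a study-sized synthetic population: 3 populations, 70 trios, rare events
ds, truth = eq.simulate_dataset(eq.study_config(seed=7))

phased = eq.phase_population(ds)
inv = eq.haplotype_inventory(phased, ds)
print(inv.totals())                      # distinct full haplotypes per population
# {'Pop1': 68, 'Pop2': 26, 'Pop3': 30}

calls = eq.call_events(ds, phased)
s = eq.event_frequencies(calls, ds, "Pop1")
print(s.n_meioses, s.counts)
# 86 {'recombination': 4, 'conversion': 4, 'insertion': 1, 'deletion': 2}
print(round(s.recombination_frequency, 1), round(s.new_haplotype_ratio, 1))
# 4.7 9.3    (percent of the 86 meioses)

res = eq.amova(ds, n_perm=199, seed=1)
print(round(res.levels["among_populations"].percent, 1), round(res.phi_pt, 3))
# 11.9 0.119  (11.9% of molecular variance among populations, p = 0.005)

fst, p = eq.pairwise_fst(ds, "Pop2", "Pop3", n_perm=99, seed=2)
print(round(fst, 3))
# 0.11
```

86 meioses is 43 full trios × 2 parent–offspring pairs; each event
frequency is `100 × (transmissions carrying that event) / meioses`. The
AMOVA percentage is the among-population variance component over the total
after truncating negative components to zero.

The same operations are available from the shell via the `equimhc` command
(`simulate`, `validate`, `export-genepop`, `stats`, `phase`, `events`,
`diff`, `deltak`); every stochastic subcommand takes an explicit `--seed`.

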