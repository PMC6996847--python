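"""Per-locus diversity statistics.

Implements from first principles the panel of statistics usually obtained
from Cervus/Genepop/Fstat/GenAlEx style tools: allele frequencies, observed
and unbiased expected heterozygosity, polymorphism information content,
inbreeding coefficient Fis, hypergeometric-rarefaction allelic richness,
effective/private allele counts, the Chakraborty null-allele estimator, a
populations-by-alleles chi-square homogeneity test, and the second-difference
(ΔK) criterion for choosing the number of genetic clusters from clustering
log-likelihoods.

Conventions
-----------
* Missing loci are dropped per statistic (pairwise deletion), so each locus
  has its own typed-individual count, as in Cervus-style outputs.
* He uses the small-sample correction 2n/(2n-1) on the gene diversity
  1 - sum(p^2).
* Fis defaults to 1 - Ho/He; the Weir-Cockerham per-locus f is available
  as an alternative estimator.
* Monomorphic loci yield p = 1 with a "not testable" flag rather than NA so
  tabulations never silently drop rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import PopulationDataset, UndefinedStatisticError
from .hwe import hwe_exact_test


@dataclass
class AlleleFreqTable:
    """Allele relative frequencies at one locus in one pool of individuals."""

    locus: str
    counts: dict[int, int]
    n_genes: int

    @property
    def freqs(self) -> dict[int, float]:
        return {a: c / self.n_genes for a, c in self.counts.items()}

    @property
    def n_alleles(self) -> int:
        return len(self.counts)


def _typed(dataset: PopulationDataset, population, locus: str):
    return [ind for ind in dataset.subset(population) if ind.genotype[locus] is not None]


def allele_frequencies(
    dataset: PopulationDataset, population=None, locus: str = None
) -> AlleleFreqTable:
    """Count each typed individual's two alleles; frequencies = counts / 2n."""
    typed = _typed(dataset, population, locus)
    if not typed:
        raise UndefinedStatisticError(f"no typed individuals at {locus}")
    counts: dict[int, int] = {}
    for ind in typed:
        for a in ind.genotype[locus]:
            counts[a] = counts.get(a, 0) + 1
    return AlleleFreqTable(locus=locus, counts=dict(sorted(counts.items())),
                           n_genes=2 * len(typed))


def observed_heterozygosity(dataset: PopulationDataset, population, locus: str) -> float:
    """Fraction of typed individuals carrying two distinct alleles."""
    typed = _typed(dataset, population, locus)
    if not typed:
        raise UndefinedStatisticError(f"no typed individuals at {locus}")
    return sum(1 for ind in typed if ind.genotype[locus][0] != ind.genotype[locus][1]) / len(typed)


def expected_heterozygosity(freqs: AlleleFreqTable) -> float:
    """Unbiased gene diversity He = (2n / (2n-1)) * (1 - sum p^2)."""
    n = freqs.n_genes
    if n < 2:
        raise UndefinedStatisticError("need at least 2 genes for He")
    s = sum(p * p for p in freqs.freqs.values())
    return n / (n - 1) * (1.0 - s)


def pic(freqs: AlleleFreqTable) -> float:
    """Polymorphism information content, 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2."""
    p = list(freqs.freqs.values())
    s2 = sum(x * x for x in p)
    cross = sum(2.0 * p[i] ** 2 * p[j] ** 2 for i in range(len(p)) for j in range(i + 1, len(p)))
    return 1.0 - s2 - cross


def fis(ho: float, he: float) -> float:
    """Locus inbreeding coefficient Fis = 1 - Ho/He (heterozygote deficit)."""
    if he <= 0:
        raise UndefinedStatisticError("Fis undefined when He = 0")
    return 1.0 - ho / he


def fis_weir_cockerham(dataset: PopulationDataset, population, locus: str) -> float:
    """Weir-Cockerham per-locus small-f (single-population estimator).

    Alternative to the ratio form; averages the per-allele variance
    components a-la Weir & Cockerham within a single sample.
    """
    typed = _typed(dataset, population, locus)
    if len(typed) < 2:
        raise UndefinedStatisticError("need >= 2 typed individuals")
    n = len(typed)
    table = allele_frequencies(dataset, population, locus)
    num = den = 0.0
    for a, p in table.freqs.items():
        # observed frequency of heterozygotes carrying allele a
        h_a = sum(
            1 for ind in typed
            if a in ind.genotype[locus] and ind.genotype[locus][0] != ind.genotype[locus][1]
        ) / n
        s2 = p * (1 - p) - h_a / 4.0
        b = n / (n - 1.0) * (p * (1 - p) - (n - 1.0) / n * h_a / 4.0) - h_a / 4.0
        c = h_a / 2.0
        num += b
        den += b + c
    if den == 0:
        raise UndefinedStatisticError("monomorphic locus")
    return num / den


def allelic_richness(
    dataset: PopulationDataset, population, locus: str, g: int
) -> float:
    """Rarefied allelic richness at standard sample size g genes.

    AR = sum_a [1 - C(N - N_a, g) / C(N, g)]: the expected number of distinct
    alleles in a hypergeometric subsample of g genes from the N observed.
    At g = N this equals the raw allele count.
    """
    table = allele_frequencies(dataset, population, locus)
    N = table.n_genes
    if g > N:
        raise ValueError(f"rarefaction size g={g} exceeds gene count N={N}")
    if g < 1:
        raise ValueError("g must be >= 1")
    denom = math.comb(N, g)
    return sum(1.0 - math.comb(N - na, g) / denom if N - na >= g else 1.0
               for na in table.counts.values())


def effective_and_private_alleles(
    dataset: PopulationDataset, population
) -> tuple[float, float, float]:
    """(Na, Ne, Np): mean alleles/locus, mean effective alleles 1/sum p^2,
    and mean private alleles per locus for one population.

    A private allele is observed in exactly one population of the dataset.
    """
    pops = dataset.populations
    if len(pops) < 2:
        raise UndefinedStatisticError("private alleles need >= 2 populations")
    na_vals, ne_vals, np_vals = [], [], []
    for locus in dataset.panel.names:
        table = allele_frequencies(dataset, population, locus)
        na_vals.append(table.n_alleles)
        ne_vals.append(1.0 / sum(p * p for p in table.freqs.values()))
        others: set[int] = set()
        for other in pops:
            if other == population:
                continue
            typed = _typed(dataset, other, locus)
            for ind in typed:
                others.update(ind.genotype[locus])
        np_vals.append(sum(1 for a in table.counts if a not in others))
    return (float(np.mean(na_vals)), float(np.mean(ne_vals)), float(np.mean(np_vals)))


def null_allele_frequency(ho: float, he: float) -> float:
    """Chakraborty null-allele estimator r = (He - Ho) / (He + Ho).

    Negative values indicate heterozygote excess rather than a null allele.
    """
    if ho + he <= 0:
        raise UndefinedStatisticError("Ho + He must be positive")
    return (he - ho) / (he + ho)


def allele_freq_homogeneity_test(
    dataset: PopulationDataset, locus: str, n_loci_tested: int | None = None
) -> tuple[float, int, float, float]:
    """Chi-square homogeneity of allele (gene) counts across populations.

    Returns (chi2, df, p, p_bonferroni) where the Bonferroni factor is the
    number of loci tested in the run (defaults to the panel size).
    """
    m = n_loci_tested if n_loci_tested is not None else len(dataset.panel)
    tables = []
    for pop in dataset.populations:
        try:
            t = allele_frequencies(dataset, pop, locus)
        except UndefinedStatisticError:
            continue  # population with 0 typed genes is excluded
        tables.append(t)
    if len(tables) < 2:
        raise UndefinedStatisticError("need >= 2 populations typed at locus")
    alleles = sorted({a for t in tables for a in t.counts})
    mat = np.array([[t.counts.get(a, 0) for a in alleles] for t in tables], dtype=float)
    mat = mat[:, mat.sum(axis=0) > 0]
    if mat.shape[1] < 2:
        return 0.0, 0, 1.0, 1.0
    chi2, p, df, _ = sps.chi2_contingency(mat, correction=False)
    return float(chi2), int(df), float(p), float(min(1.0, p * m))


# ---------------------------------------------------------------------------
# per-locus stats table
# ---------------------------------------------------------------------------

@dataclass
class LocusStats:
    """The full per-locus panel of diversity statistics for one pool."""

    locus: str
    n_typed: int
    n_alleles: int
    Ho: float
    He: float
    PIC: float
    Fis: float
    Fis_wc: float | None
    AR: float
    Ne: float
    null_freq: float
    hwe_p: float
    hwe_testable: bool


def locus_stats(
    dataset: PopulationDataset,
    population=None,
    rarefaction_g: int | None = None,
    n_mc: int = 100_000,
    seed: int = 0,
) -> list[LocusStats]:
    """Compute the Table-1/Table-2 style statistics panel for one pool.

    ``rarefaction_g`` defaults, per locus, to the minimum gene count across
    the dataset's populations (so the smallest population's AR is its raw
    allele count).
    """
    out = []
    for locus in dataset.panel.names:
        table = allele_frequencies(dataset, population, locus)
        ho = observed_heterozygosity(dataset, population, locus)
        he = expected_heterozygosity(table)
        if rarefaction_g is None:
            g = min(
                2 * len(_typed(dataset, pop, locus)) for pop in dataset.populations
            )
        else:
            g = rarefaction_g
        g = min(g, table.n_genes)
        try:
            f = fis(ho, he)
        except UndefinedStatisticError:
            f = float("nan")
        try:
            fwc = fis_weir_cockerham(dataset, population, locus)
        except UndefinedStatisticError:
            fwc = None
        try:
            null = null_allele_frequency(ho, he)
        except UndefinedStatisticError:
            null = float("nan")
        p, testable = hwe_exact_test(dataset, population, locus, n_mc=n_mc, seed=seed)
        out.append(
            LocusStats(
                locus=locus,
                n_typed=table.n_genes // 2,
                n_alleles=table.n_alleles,
                Ho=ho,
                He=he,
                PIC=pic(table),
                Fis=f,
                Fis_wc=fwc,
                AR=allelic_richness(dataset, population, locus, g),
                Ne=1.0 / sum(p_ * p_ for p_ in table.freqs.values()),
                null_freq=null,
                hwe_p=p,
                hwe_testable=testable,
            )
        )
    return out


def stats_frame(stats: list[LocusStats]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in stats])


def population_summary(dataset: PopulationDataset) -> pd.DataFrame:
    """Table-3 style per-population summary: Na, Ne, Np and mean He over loci."""
    rows = []
    for pop in dataset.populations:
        na, ne, npa = effective_and_private_alleles(dataset, pop)
        he = float(
            np.mean(
                [
                    expected_heterozygosity(allele_frequencies(dataset, pop, locus))
                    for locus in dataset.panel.names
                ]
            )
        )
        rows.append({"population": pop, "Na": na, "Ne": ne, "Np": npa, "He": he})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Evanno ΔK
# ---------------------------------------------------------------------------

@dataclass
class DeltaKResult:
    """Second-difference statistics over clustering log-likelihood replicates."""

    table: pd.DataFrame  # columns: K, mean_lnP, sd_lnP, l2, delta_k
    best_k: int


def evanno_delta_k(lnp: Mapping[int, Sequence[float]]) -> DeltaKResult:
    """Evanno ΔK from per-K replicate log-likelihoods.

    ΔK(K) = |mean lnP(K+1) - 2 mean lnP(K) + mean lnP(K-1)| / sd(lnP(K));
    defined only for interior K; the selected K maximizes ΔK. A zero
    replicate sd makes ΔK infinite and is flagged via ``math.inf``.
    """
    ks = sorted(lnp)
    if len(ks) < 3 or any(b - a != ks[1] - ks[0] for a, b in zip(ks, ks[1:])):
        if len(ks) < 3:
            raise ValueError("need >= 3 consecutive K values")
    if any(len(lnp[k]) < 2 for k in ks):
        raise ValueError("need >= 2 replicates per K")
    mean = {k: float(np.mean(lnp[k])) for k in ks}
    sd = {k: float(np.std(lnp[k], ddof=1)) for k in ks}
    rows = []
    for i, k in enumerate(ks):
        if 0 < i < len(ks) - 1:
            l2 = abs(mean[ks[i + 1]] - 2 * mean[k] + mean[ks[i - 1]])
            dk = l2 / sd[k] if sd[k] > 0 else math.inf
        else:
            l2, dk = math.nan, math.nan
        rows.append({"K": k, "mean_lnP": mean[k], "sd_lnP": sd[k], "l2": l2, "delta_k": dk})
    table = pd.DataFrame(rows)
    interior = table.dropna(subset=["delta_k"])
    best = int(interior.loc[interior["delta_k"].idxmax(), "K"])
    return DeltaKResult(table=table, best_k=best)
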