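"""Exact Hardy-Weinberg and genotypic linkage-disequilibrium tests.

The HWE test is the conditional exact (probability) test: conditioning on the
observed allele counts, the probability of a genotype table is

    P(table) = n! 2^h prod_a(n_a!) / (prod_gg n_gg! (2n)!)

with h the number of heterozygous individuals. The p-value is the total
probability of tables no more probable than the observed one. Small problems
are fully enumerated; larger ones fall back to Monte-Carlo shuffling of the
gene vector (random re-pairings of the 2n genes), which samples tables from
exactly that conditional distribution.

The LD test is the genotypic contingency-table log-likelihood-ratio (G) test
with a permutation null: one locus's genotypes are permuted across
individuals, breaking any between-locus association while preserving both
single-locus genotype distributions.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np

from .data import PopulationDataset

_LOG2 = math.log(2.0)
_TOL = 1e-9


def _lfact(n: int) -> float:
    return math.lgamma(n + 1)


def _table_logprob_core(genotype_counts: Mapping[tuple[int, int], int]) -> float:
    """h*log2 - sum(log n_gg!): the table-dependent part of log P(table)."""
    h = sum(c for (a, b), c in genotype_counts.items() if a != b)
    return h * _LOG2 - sum(_lfact(c) for c in genotype_counts.values())


class _EnumerationOverflow(Exception):
    pass


def enumerate_hwe_tables(allele_counts: list[int], cap: int = 100_000):
    """Yield all genotype tables consistent with the given allele counts.

    Tables are dicts (i, j) -> count over allele indices i <= j. Raises
    ``_EnumerationOverflow`` if more than ``cap`` tables exist.
    """
    k = len(allele_counts)
    pairs = [(i, j) for i in range(k) for j in range(i, k)]
    out: list[dict[tuple[int, int], int]] = []
    remaining = list(allele_counts)

    def rec(idx: int, current: dict[tuple[int, int], int]) -> None:
        if idx == len(pairs):
            if all(r == 0 for r in remaining):
                out.append(dict(current))
                if len(out) > cap:
                    raise _EnumerationOverflow
            return
        i, j = pairs[idx]
        last_for_i = j == k - 1
        if i == j:
            hi = remaining[i] // 2
            lo = hi if (i == k - 1) else 0  # final pair of final allele is forced
            if i == k - 1 and remaining[i] % 2 != 0:
                return
            for m in range(lo, hi + 1):
                if i == k - 1 and 2 * m != remaining[i]:
                    continue
                remaining[i] -= 2 * m
                if m:
                    current[(i, j)] = m
                rec(idx + 1, current)
                current.pop((i, j), None)
                remaining[i] += 2 * m
        else:
            hi = min(remaining[i], remaining[j])
            if last_for_i:
                ms = [remaining[i]] if remaining[i] <= remaining[j] else []
            else:
                ms = range(0, hi + 1)
            for m in ms:
                remaining[i] -= m
                remaining[j] -= m
                if m:
                    current[(i, j)] = m
                rec(idx + 1, current)
                current.pop((i, j), None)
                remaining[i] += m
                remaining[j] += m

    rec(0, {})
    return out


def hwe_exact_p(genotype_counts: Mapping[tuple[int, int], int], cap: int = 100_000) -> float:
    """Full-enumeration exact probability-test p-value for one genotype table."""
    counts = {tuple(sorted(k)): v for k, v in genotype_counts.items() if v}
    alleles = sorted({a for pair in counts for a in pair})
    idx = {a: i for i, a in enumerate(alleles)}
    counts = {(idx[a], idx[b]): v for (a, b), v in counts.items()}
    allele_n = [0] * len(alleles)
    for (i, j), c in counts.items():
        allele_n[i] += c
        allele_n[j] += c
    if len(alleles) < 2:
        return 1.0
    obs = _table_logprob_core(counts)
    tables = enumerate_hwe_tables(allele_n, cap=cap)
    cores = np.array([_table_logprob_core(t) for t in tables])
    # normalize: P(table) proportional to n!/... * exp(core); shared factors cancel
    w = np.exp(cores - cores.max())
    w /= w.sum()
    return min(1.0, float(w[cores <= obs + _TOL].sum()))


def hwe_mc_p(
    genotype_counts: Mapping[tuple[int, int], int], n_mc: int, seed: int
) -> float:
    """Monte-Carlo p by shuffling the gene vector and re-pairing genes."""
    counts = {tuple(sorted(k)): v for k, v in genotype_counts.items() if v}
    genes: list[int] = []
    for (a, b), c in counts.items():
        genes.extend([a, b] * c)
    genes_arr = np.array(genes)
    obs = _table_logprob_core(counts)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(genes_arr)
        pairs = np.sort(perm.reshape(-1, 2), axis=1)
        _, cnt = np.unique(pairs, axis=0, return_counts=True)
        het = int((pairs[:, 0] != pairs[:, 1]).sum())
        core = het * _LOG2 - sum(_lfact(int(c)) for c in cnt)
        if core <= obs + _TOL:
            hits += 1
    return (hits + 1) / (n_mc + 1)


def genotype_counts(
    dataset: PopulationDataset, population, locus: str
) -> dict[tuple[int, int], int]:
    counts: dict[tuple[int, int], int] = {}
    for ind in dataset.subset(population):
        g = ind.genotype[locus]
        if g is None:
            continue
        counts[g] = counts.get(g, 0) + 1
    return counts


def hwe_exact_test(
    dataset: PopulationDataset,
    population,
    locus: str,
    n_mc: int = 100_000,
    seed: int = 0,
    max_tables: int = 100_000,
) -> tuple[float, bool]:
    """Exact HWE test; returns (p, testable).

    Monomorphic loci (or <2 typed individuals) return p = 1 with
    ``testable=False``. Enumeration is used while the table space stays below
    ``max_tables``; otherwise Monte-Carlo with ``n_mc`` gene-vector shuffles.
    """
    counts = genotype_counts(dataset, population, locus)
    alleles = {a for pair in counts for a in pair}
    n = sum(counts.values())
    if len(alleles) < 2 or n < 2:
        return 1.0, False
    try:
        return hwe_exact_p(counts, cap=max_tables), True
    except _EnumerationOverflow:
        return hwe_mc_p(counts, n_mc=n_mc, seed=seed), True


# ---------------------------------------------------------------------------
# genotypic LD
# ---------------------------------------------------------------------------

def _g_statistic(codes_a: np.ndarray, codes_b: np.ndarray) -> float:
    table = np.zeros((codes_a.max() + 1, codes_b.max() + 1))
    np.add.at(table, (codes_a, codes_b), 1.0)
    total = table.sum()
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows @ cols / total
    mask = table > 0
    return float(2.0 * (table[mask] * np.log(table[mask] / expected[mask])).sum())


def ld_pair_test(
    dataset: PopulationDataset,
    population,
    locus_a: str,
    locus_b: str,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, bool]:
    """Genotypic LD G-test between two loci with a permutation null.

    Returns (p, testable); either locus being monomorphic in the tested pool
    makes the pair untestable (p = 1, flag False). The p-value uses the
    add-one correction (1 + hits) / (1 + n_perm).
    """
    pairs = [
        (ind.genotype[locus_a], ind.genotype[locus_b])
        for ind in dataset.subset(population)
        if ind.genotype[locus_a] is not None and ind.genotype[locus_b] is not None
    ]
    if not pairs:
        return 1.0, False
    for side in (0, 1):
        alleles = {a for g in pairs for a in g[side]}
        if len(alleles) < 2:
            return 1.0, False
    cats_a = {g: i for i, g in enumerate(sorted({a for a, _ in pairs}))}
    cats_b = {g: i for i, g in enumerate(sorted({b for _, b in pairs}))}
    codes_a = np.array([cats_a[a] for a, _ in pairs])
    codes_b = np.array([cats_b[b] for _, b in pairs])
    obs = _g_statistic(codes_a, codes_b)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if _g_statistic(codes_a, rng.permutation(codes_b)) >= obs - _TOL:
            hits += 1
    return (hits + 1) / (n_perm + 1), True
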