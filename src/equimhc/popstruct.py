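"""Between-population differentiation: Nei identity/distance, AMOVA, Fst.

The AMOVA is the hierarchical (Excoffier-style) partition of squared genetic
distances for codominant data at three levels: among populations, among
individuals within populations, and within individuals. The distance metric
is the per-locus allele mismatch count (no repeat-size weighting), summed
over loci, with missing loci skipped and the sum rescaled by the panel size
over the shared typed count (pairwise deletion). Phi-statistics are ratios
of the resulting variance components; significance is by permuting
individuals among groups.

Nei's genetic identity uses the unbiased (sample-size corrected)
within-population homozygosities, I = Jxy / sqrt(Jx Jy) with each J averaged
over loci, and D = -ln I.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data import PopulationDataset, UndefinedStatisticError
from .diversity import AlleleFreqTable, allele_frequencies

_TOL = 1e-12


# ---------------------------------------------------------------------------
# Nei identity / distance
# ---------------------------------------------------------------------------

@dataclass
class DistanceResult:
    pair: tuple[str, str]
    fst: float           # clamped to [0, 1]
    fst_raw: float
    fst_p: float
    nei_identity: float
    nei_distance: float  # -ln(I); inf when I == 0


def nei_identity_distance(
    freqs_a: Mapping[str, AlleleFreqTable], freqs_b: Mapping[str, AlleleFreqTable]
) -> tuple[float, float]:
    """Unbiased Nei genetic identity I and distance D = -ln I.

    ``freqs_a``/``freqs_b`` map locus name -> allele frequency table for each
    population; loci present in both are used. Within-population J values use
    the unbiased estimator (2n * sum(p^2) - 1) / (2n - 1).
    """
    shared = [l for l in freqs_a if l in freqs_b]
    if not shared:
        raise UndefinedStatisticError("no shared locus between populations")
    jxy, jx, jy = [], [], []
    for locus in shared:
        fa, fb = freqs_a[locus], freqs_b[locus]
        pa, pb = fa.freqs, fb.freqs
        jxy.append(sum(pa.get(al, 0.0) * pb.get(al, 0.0) for al in set(pa) | set(pb)))
        na, nb = fa.n_genes, fb.n_genes
        jx.append((na * sum(p * p for p in pa.values()) - 1.0) / (na - 1.0))
        jy.append((nb * sum(p * p for p in pb.values()) - 1.0) / (nb - 1.0))
    denom = math.sqrt(float(np.mean(jx)) * float(np.mean(jy)))
    identity = float(np.mean(jxy)) / denom if denom > 0 else 0.0
    identity = min(identity, 1.0)
    distance = -math.log(identity) if identity > 0 else math.inf
    return identity, distance


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaLevel:
    df: int
    ss: float
    ms: float
    variance: float        # raw (may be negative)
    variance_trunc: float  # truncated at 0
    percent: float         # of truncated total; nan when total is 0


@dataclass
class AmovaResult:
    levels: dict[str, AmovaLevel]  # among_populations / among_individuals / within_individuals
    phi_pt: float
    phi_is: float
    phi_it: float
    p_values: dict[str, float]
    degenerate: bool               # total variance 0 (e.g. clonal data)
    negative_components: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, lv in self.levels.items():
            rows.append(
                {"level": name, "df": lv.df, "SS": lv.ss, "MS": lv.ms,
                 "variance": lv.variance, "percent": lv.percent}
            )
        return pd.DataFrame(rows)


def _allele_matrix(dataset: PopulationDataset, individuals):
    """Two (N, L) integer arrays of allele sizes; -1 encodes missing."""
    L = len(dataset.panel)
    a1 = np.full((len(individuals), L), -1, dtype=np.int64)
    a2 = np.full((len(individuals), L), -1, dtype=np.int64)
    for i, ind in enumerate(individuals):
        for j, name in enumerate(dataset.panel.names):
            g = ind.genotype[name]
            if g is not None:
                a1[i, j], a2[i, j] = g
    return a1, a2


def _distance_components(a1: np.ndarray, a2: np.ndarray):
    """(cross, within): rescaled mismatch sums between and within individuals.

    cross[i, j] = sum over loci typed in both of the 4 allele cross-pair
    mismatch indicators, rescaled by L / L_shared; within[i] = heterozygous
    locus count rescaled by L / L_typed. Together these give every squared
    distance among the 2N gametes without requiring phase.
    """
    n, L = a1.shape
    typed = a1 >= 0
    within_raw = ((a1 != a2) & typed).sum(axis=1).astype(float)
    l_typed = typed.sum(axis=1)
    within = np.where(l_typed > 0, within_raw * L / np.maximum(l_typed, 1), 0.0)

    cross = np.zeros((n, n))
    for i in range(n):
        shared = typed[i] & typed  # (n, L)
        mm = (
            (a1[i] != a1).astype(np.int64)
            + (a1[i] != a2)
            + (a2[i] != a1)
            + (a2[i] != a2)
        )
        raw = np.where(shared, mm, 0).sum(axis=1).astype(float)
        l_sh = shared.sum(axis=1)
        cross[i] = np.where(l_sh > 0, raw * L / np.maximum(l_sh, 1), 0.0)
    np.fill_diagonal(cross, 0.0)
    return cross, within


def _amova_from_components(cross, within, groups, group_ids):
    """Three-level AMOVA sums of squares and variance components."""
    n = len(within)
    k = len(group_ids)
    total_gametes = 2 * n

    ss_wi = within.sum() / 2.0
    sum_cross_total = cross.sum() / 2.0  # i<j pairs
    ss_total = (sum_cross_total + within.sum()) / total_gametes

    ss_wp = 0.0
    m_sizes = []
    for g in group_ids:
        mask = groups == g
        m = int(mask.sum())
        m_sizes.append(2 * m)
        sub_cross = cross[np.ix_(mask, mask)].sum() / 2.0
        ss_wp += (sub_cross + within[mask].sum()) / (2 * m)
    ss_ai = ss_wp - ss_wi
    ss_ap = ss_total - ss_wp

    df_ap, df_ai, df_wi = k - 1, n - k, n
    ms_ap = ss_ap / df_ap if df_ap else 0.0
    ms_ai = ss_ai / df_ai if df_ai else 0.0
    ms_wi = ss_wi / df_wi if df_wi else 0.0

    M = float(total_gametes)
    n0 = (M - sum(m * m for m in m_sizes) / M) / (k - 1)
    var_c = ms_wi
    var_b = (ms_ai - ms_wi) / 2.0
    var_a = (ms_ap - ms_ai) / n0 if n0 > 0 else 0.0
    return (
        {"among_populations": (df_ap, ss_ap, ms_ap, var_a),
         "among_individuals": (df_ai, ss_ai, ms_ai, var_b),
         "within_individuals": (df_wi, ss_wi, ms_wi, var_c)},
    )


def _phi_pt(levels) -> float:
    va = max(levels["among_populations"][3], 0.0)
    vb = max(levels["among_individuals"][3], 0.0)
    vc = max(levels["within_individuals"][3], 0.0)
    tot = va + vb + vc
    return va / tot if tot > 0 else float("nan")


def amova(
    dataset: PopulationDataset,
    grouping: Mapping[str, str] | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> AmovaResult:
    """Three-level codominant AMOVA with a permutation test on Phi-PT.

    ``grouping`` maps individual id -> group label; by default population
    labels are used. Populations (groups) of size 1 are excluded with a
    warning-style silent drop reflected in the df. Negative variance
    components are reported raw and truncated to 0 for the percents.
    """
    if grouping is None:
        grouping = {ind.id: ind.population for ind in dataset.individuals}
    else:
        missing = [ind.id for ind in dataset.individuals if ind.id not in grouping]
        if missing:
            raise KeyError(f"individuals without group assignment: {missing[:5]}")
    # drop singleton groups
    sizes: dict[str, int] = {}
    for ind in dataset.individuals:
        g = grouping[ind.id]
        sizes[g] = sizes.get(g, 0) + 1
    keep = {g for g, s in sizes.items() if s >= 2}
    individuals = [ind for ind in dataset.individuals if grouping[ind.id] in keep]
    group_ids = sorted(keep)
    if len(group_ids) < 2:
        raise UndefinedStatisticError("AMOVA needs >= 2 groups of size >= 2")
    groups = np.array([group_ids.index(grouping[ind.id]) for ind in individuals])
    gid = np.arange(len(group_ids))

    a1, a2 = _allele_matrix(dataset, individuals)
    cross, within = _distance_components(a1, a2)
    (levels_raw,) = _amova_from_components(cross, within, groups, gid)

    va, vb, vc = (levels_raw[k][3] for k in
                  ("among_populations", "among_individuals", "within_individuals"))
    trunc = [max(v, 0.0) for v in (va, vb, vc)]
    total = sum(trunc)
    degenerate = total <= _TOL
    negative = [name for name, v in zip(
        ("among_populations", "among_individuals", "within_individuals"),
        (va, vb, vc)) if v < 0]

    levels = {}
    for name, v, vt in zip(
        ("among_populations", "among_individuals", "within_individuals"),
        (va, vb, vc), trunc,
    ):
        df, ss, ms, _ = levels_raw[name]
        pct = 100.0 * vt / total if not degenerate else float("nan")
        levels[name] = AmovaLevel(df=df, ss=ss, ms=ms, variance=v,
                                  variance_trunc=vt, percent=pct)

    phi_pt = trunc[0] / total if not degenerate else float("nan")
    phi_it = (trunc[0] + trunc[1]) / total if not degenerate else float("nan")
    phi_is = trunc[1] / (trunc[1] + trunc[2]) if (trunc[1] + trunc[2]) > 0 else float("nan")

    # permutation test: shuffle individuals among groups (sizes preserved)
    p = float("nan")
    if n_perm > 0 and not degenerate:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            perm_groups = rng.permutation(groups)
            (lv,) = _amova_from_components(cross, within, perm_groups, gid)
            if _phi_pt(lv) >= phi_pt - _TOL:
                hits += 1
        p = (hits + 1) / (n_perm + 1)

    return AmovaResult(
        levels=levels,
        phi_pt=phi_pt,
        phi_is=phi_is,
        phi_it=phi_it,
        p_values={"phi_pt": p},
        degenerate=degenerate,
        negative_components=negative,
    )


def cluster_regroup_amova(
    dataset: PopulationDataset,
    assignments: Mapping[str, str],
    n_perm: int = 999,
    seed: int = 0,
) -> AmovaResult:
    """AMOVA with external cluster assignments as the grouping level.

    Typically used to re-partition variance across clusters inferred by an
    external Bayesian admixture run. Every individual must be assigned.
    """
    return amova(dataset, grouping=assignments, n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# pairwise Fst
# ---------------------------------------------------------------------------

def weir_cockerham_theta(dataset: PopulationDataset, pops: list[str]) -> float:
    """Multi-allele Weir-Cockerham theta over the panel for the given pops."""
    num = den = 0.0
    r = len(pops)
    for locus in dataset.panel.names:
        tables = []
        for pop in pops:
            try:
                tables.append((pop, allele_frequencies(dataset, pop, locus)))
            except UndefinedStatisticError:
                pass
        if len(tables) < 2:
            continue
        ns = [t.n_genes / 2 for _, t in tables]
        nbar = sum(ns) / r
        nc = (r * nbar - sum(x * x for x in ns) / (r * nbar)) / (r - 1)
        alleles = sorted({a for _, t in tables for a in t.counts})
        for al in alleles:
            ps = [t.freqs.get(al, 0.0) for _, t in tables]
            hs = []
            for (pop, t), n_i in zip(tables, ns):
                het = sum(
                    1 for ind in dataset.subset(pop)
                    if ind.genotype[locus] is not None
                    and al in ind.genotype[locus]
                    and ind.genotype[locus][0] != ind.genotype[locus][1]
                )
                hs.append(het / n_i)
            pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
            s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
            hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
            )
            c = hbar / 2.0
            num += a
            den += a + b + c
    if den == 0:
        raise UndefinedStatisticError("no variation across the panel")
    return num / den


def pairwise_fst(
    dataset: PopulationDataset,
    pop_a: str,
    pop_b: str,
    n_perm: int = 999,
    seed: int = 0,
    estimator: str = "phi_pt",
) -> tuple[float, float]:
    """Pairwise differentiation between two populations.

    The default estimator is Phi-PT from the AMOVA restricted to the pair
    (identical to :func:`amova` on the two populations); ``estimator="wc"``
    gives the Weir-Cockerham theta instead (no permutation p in that case).
    Returns (fst, p).
    """
    individuals = dataset.subset([pop_a, pop_b])
    shared = any(
        any(ind.genotype[l] is not None for ind in dataset.subset(pop_a))
        and any(ind.genotype[l] is not None for ind in dataset.subset(pop_b))
        for l in dataset.panel.names
    )
    if not shared:
        raise UndefinedStatisticError("no locus typed in both populations")
    if estimator == "wc":
        return weir_cockerham_theta(dataset, [pop_a, pop_b]), float("nan")
    sub = PopulationDataset(panel=dataset.panel,
                            individuals=[Individual_copy(i) for i in individuals])
    res = amova(sub, n_perm=n_perm, seed=seed)
    return res.phi_pt, res.p_values["phi_pt"]


def Individual_copy(ind):
    from .data import Individual

    return Individual(id=ind.id, population=ind.population,
                      genotype=dict(ind.genotype), sire_id=None, dam_id=None)


def distance_panel(
    dataset: PopulationDataset, n_perm: int = 999, seed: int = 0
) -> list[DistanceResult]:
    """All pairwise Fst (Phi-PT) + Nei I/D results over the dataset's pops."""
    pops = dataset.populations
    out = []
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            pa, pb = pops[i], pops[j]
            fa = {l: allele_frequencies(dataset, pa, l) for l in dataset.panel.names}
            fb = {l: allele_frequencies(dataset, pb, l) for l in dataset.panel.names}
            identity, dist = nei_identity_distance(fa, fb)
            fst_raw, p = pairwise_fst(dataset, pa, pb, n_perm=n_perm, seed=seed + i * 31 + j)
            out.append(
                DistanceResult(
                    pair=(pa, pb),
                    fst=min(max(fst_raw, 0.0), 1.0),
                    fst_raw=fst_raw,
                    fst_p=p,
                    nei_identity=identity,
                    nei_distance=dist,
                )
            )
    return out
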