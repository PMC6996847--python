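"""Meiotic event calling: recombination, gene conversion, indels.

Each observed transmission (one parent -> one offspring haplotype) is
compared with the parent's two established haplotypes and explained as the
minimum-cost combination of

* a mosaic of the two parental haplotypes (crossovers; each breakpoint is
  localized to the interval between the flanking *informative* loci —
  loci where the parental haplotypes differ; uninformative loci can never
  anchor a breakpoint, they only widen the interval),
* short internal segments copied from the homologous haplotype
  (gene conversion; tracts of at most two loci),
* single-locus shifts by a whole number of repeat units (insertion when the
  fragment grows, deletion when it shrinks).

Cost ordering: no event < single conversion = single indel < one-breakpoint
recombination < two breakpoints < conversion+indel < other combinations.
This ranking is lexicographic — fewest event records first (a recombination
with several breakpoints is one event), then fewest breakpoints, then
fewest point events. A single-locus switch at a terminal
panel locus ties between a one-breakpoint recombination and a conversion;
it is called recombination unless the offspring demonstrably carries both
alleles of that parent at the locus (a non-reciprocal duplication pattern),
in which case conversion. All ties are recorded. Transmissions that cannot
be explained within the budget (three breakpoints plus one point event) are
flagged unexplained, never silently dropped.

Per-meiosis frequencies use the number of parent-offspring pairs as the
denominator: a full trio contributes two meioses, a single-parent pair one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .data import PopulationDataset, UndefinedStatisticError
from .panel import LocusPanel
from .phasing import (
    CONFLICT,
    Hap,
    HaplotypeInventory,
    PhasedIndividual,
    hap_complete,
)

Allele = Optional[int]

NONE = "none"
RECOMBINATION = "recombination"
CONVERSION = "conversion"
INSERTION = "insertion"
DELETION = "deletion"
UNEXPLAINED = "unexplained"
SKIPPED = "skipped"

MAX_BREAKPOINTS = 3
MAX_INDEL_STEPS = 3


@dataclass
class MeiosisEvent:
    """One elementary genetic event observed in one transmission."""

    offspring_id: str
    parent_id: str
    parent_sex: str  # "dam" | "sire"
    type: str        # recombination / conversion / insertion / deletion
    breakpoints: list[tuple[str, str]] = field(default_factory=list)
    loci: list[str] = field(default_factory=list)
    allele_change: tuple[int, int] | None = None  # (parental, transmitted) for indels
    resulting_haplotype: Hap = ()
    is_new_haplotype: bool = False


@dataclass
class Explanation:
    """Minimum-cost account of a transmitted haplotype."""

    type: str  # none / recombination / conversion / insertion / deletion /
               # mixed / unexplained
    breakpoints: list[tuple[str, str]] = field(default_factory=list)
    conversions: list[list[str]] = field(default_factory=list)   # tracts (locus lists)
    indels: list[tuple[str, int, int]] = field(default_factory=list)  # (locus, from, to)
    cost: tuple = (0, 0, 0)  # (event records, breakpoints, point events)
    ties: list[str] = field(default_factory=list)


def explain_transmission(
    parent_haps: tuple[Sequence[Allele], Sequence[Allele]],
    transmitted: Sequence[Allele],
    panel: LocusPanel,
    offspring_genotype: Sequence | None = None,
    other_parent_genotype: Sequence | None = None,
    max_breakpoints: int = MAX_BREAKPOINTS,
    max_indel_steps: int = MAX_INDEL_STEPS,
) -> Explanation:
    """Explain one transmitted haplotype against the parent's two haplotypes.

    Only loci where both parental alleles and the transmitted allele are
    known are compared. ``offspring_genotype`` and ``other_parent_genotype``
    (per-locus pairs) are used solely for the terminal-locus duplication
    tie-break: a terminal single-locus switch is called conversion instead
    of recombination only when the offspring carries both of this parent's
    alleles *and* neither could have come from the other parent.
    """
    h1, h2 = parent_haps
    L = len(panel)
    names = panel.names

    compared = [
        l for l in range(L)
        if transmitted[l] is not None and h1[l] is not None and h2[l] is not None
    ]
    inf_cost = (float("inf"),) * 3
    if len(compared) < 2:
        return Explanation(type=UNEXPLAINED, cost=inf_cost,
                           ties=["fewer than 2 comparable loci"])

    informative: list[int] = []
    source: dict[int, int] = {}
    mismatches: list[int] = []
    for l in compared:
        t = transmitted[l]
        if h1[l] == h2[l]:
            if t != h1[l]:
                mismatches.append(l)
            continue
        if t == h1[l]:
            source[l] = 0
            informative.append(l)
        elif t == h2[l]:
            source[l] = 1
            informative.append(l)
        else:
            mismatches.append(l)

    # point events: loci matching neither parental allele
    indels: list[tuple[str, int, int]] = []
    if len(mismatches) > 1:
        return Explanation(type=UNEXPLAINED, cost=inf_cost,
                           ties=[f"{len(mismatches)} loci match neither parental allele"])
    for l in mismatches:
        unit = panel[l].repeat_unit
        t = transmitted[l]
        offsets = sorted(
            {t - h1[l], t - h2[l]}, key=lambda d: (abs(d), d)
        )
        chosen = None
        for d in offsets:
            if d != 0 and d % unit == 0 and abs(d) // unit <= max_indel_steps:
                chosen = d
                break
        if chosen is None:
            return Explanation(
                type=UNEXPLAINED, cost=inf_cost,
                ties=[f"{names[l]}: offset not a small repeat-unit multiple"],
            )
        src_allele = t - chosen
        indels.append((names[l], src_allele, t))

    ties: list[str] = []
    conversions: list[list[str]] = []
    breakpoints: list[tuple[str, str]] = []

    if informative:
        # Candidate conversion tracts: 1-2 consecutive informative loci of
        # one source, spanning at most two panel positions. A conversion
        # requires *demonstrated* same-haplotype context on both sides, so
        # a tract may never include the first or last informative locus
        # (an uninformative flank cannot demonstrate context).
        cands: list[tuple[int, ...]] = []
        for i in range(len(informative)):
            for j in (i, i + 1):
                if j >= len(informative):
                    continue
                cov = tuple(informative[i : j + 1])
                if cov[-1] - cov[0] + 1 > 2:
                    continue
                if cov[0] <= informative[0] or cov[-1] >= informative[-1]:
                    continue
                if len({source[l] for l in cov}) != 1:
                    continue
                cands.append(cov)

        # exact search: which tracts to call conversions so that
        # 2*(breakpoints) + (conversions) is minimal. The underlying mosaic
        # at a converted locus is the homolog of the observed allele, so the
        # switch count is read off the flipped source sequence directly.
        best = None
        max_tracts = min(4, len(cands))
        from itertools import combinations

        for r in range(0, max_tracts + 1):
            for combo in combinations(cands, r):
                cov_all = [l for c in combo for l in c]
                covset = set(cov_all)
                if len(covset) != len(cov_all):
                    continue
                u = [
                    (1 - source[l]) if l in covset else source[l]
                    for l in informative
                ]
                switches = sum(1 for a, b in zip(u, u[1:]) if a != b)
                if switches > max_breakpoints:
                    continue
                n_events = (1 if switches else 0) + r + len(indels)
                key = (n_events, switches, r, combo)
                if best is None or key < best[0]:
                    best = (key, combo, u)
        if best is None:
            return Explanation(type=UNEXPLAINED, cost=inf_cost,
                               ties=[f"more than {max_breakpoints} breakpoints required"])
        _, combo, u = best
        for c in combo:
            conversions.append([names[l] for l in c])
            ties.append(
                f"conversion at {names[c[0]]} preferred over a crossover pair"
            )

        # runs of the underlying source
        uruns: list[list[int]] = [[informative[0]]]
        for idx in range(1, len(informative)):
            if u[idx] == u[idx - 1]:
                uruns[-1].append(informative[idx])
            else:
                uruns.append([informative[idx]])

        # terminal single-locus segments tie between a one-breakpoint
        # recombination and a conversion: recombination by convention,
        # unless the offspring demonstrably carries both of this parent's
        # alleles at the locus while the other parent is excluded
        final: list[list[int]] = []
        for run in uruns:
            terminal = run[0] == informative[0] or run[-1] == informative[-1]
            if terminal and len(run) == 1 and len(uruns) > 1:
                l = run[0]
                dup = False
                if offspring_genotype is not None and other_parent_genotype is not None:
                    g = offspring_genotype[l]
                    og = other_parent_genotype[l]
                    parent_pair = tuple(sorted((h1[l], h2[l])))
                    dup = (
                        g is not None
                        and og is not None
                        and tuple(sorted(g)) == parent_pair
                        and h1[l] != h2[l]
                        and not (set(g) & set(og))
                    )
                if dup:
                    conversions.append([names[l]])
                    ties.append(
                        f"terminal locus {names[l]}: duplication pattern, "
                        "called conversion (tie with recombination)"
                    )
                    continue
                ties.append(
                    f"terminal locus {names[l]}: called recombination "
                    "(tie with conversion)"
                )
            final.append(run)
        # re-merge in case a dup-converted terminal segment joined its flanks
        uval = {l: u[idx] for idx, l in enumerate(informative)}
        merged: list[list[int]] = []
        for run in final:
            if merged and uval[run[0]] == uval[merged[-1][-1]]:
                merged[-1].extend(run)
            else:
                merged.append(run)
        for left, right in zip(merged, merged[1:]):
            breakpoints.append((names[left[-1]], names[right[0]]))

    if len(breakpoints) > max_breakpoints:
        return Explanation(type=UNEXPLAINED, cost=inf_cost,
                           ties=[f"more than {max_breakpoints} breakpoints required"])

    n_events = (1 if breakpoints else 0) + len(conversions) + len(indels)
    cost = (n_events, len(breakpoints), len(conversions) + len(indels))
    kinds = []
    if breakpoints:
        kinds.append(RECOMBINATION)
    if conversions:
        kinds.append(CONVERSION)
    for _, frm, to in indels:
        kinds.append(INSERTION if to > frm else DELETION)
    if not kinds:
        etype = NONE
    elif len(kinds) == 1:
        etype = kinds[0]
    else:
        etype = "mixed"
    return Explanation(
        type=etype,
        breakpoints=breakpoints,
        conversions=conversions,
        indels=indels,
        cost=cost,
        ties=ties,
    )


# ---------------------------------------------------------------------------
# dataset-level calling
# ---------------------------------------------------------------------------

@dataclass
class TransmissionRecord:
    offspring_id: str
    parent_id: str
    parent_sex: str
    population: str
    status: str  # none / events / unexplained / skipped
    events: list[MeiosisEvent] = field(default_factory=list)
    ties: list[str] = field(default_factory=list)
    resulting_haplotype: Hap = ()
    is_new_haplotype: bool = False


@dataclass
class EventCallSet:
    records: list[TransmissionRecord]
    parental_pool: dict[str, set[Hap]]  # population -> founder/parent haplotypes

    @property
    def events(self) -> list[MeiosisEvent]:
        return [e for r in self.records for e in r.events]

    def coverage(self) -> dict[str, int]:
        out = {"none": 0, "events": 0, "unexplained": 0, "skipped": 0}
        for r in self.records:
            out[r.status] += 1
        return out


def _parental_generation_pool(
    phased: list[PhasedIndividual], dataset: PopulationDataset
) -> dict[str, set[Hap]]:
    """Fully-resolved haplotypes of the non-offspring generation, per pop."""
    by_id = dataset.by_id
    pool: dict[str, set[Hap]] = {p: set() for p in dataset.populations}
    for ph in phased:
        if by_id[ph.id].is_offspring:
            continue
        for hap in (ph.hap_maternal, ph.hap_paternal):
            if hap_complete(hap):
                pool[ph.population].add(hap)
    return pool


def call_events(
    dataset: PopulationDataset, phased: list[PhasedIndividual]
) -> EventCallSet:
    """Classify every resolvable parent-offspring transmission.

    A transmission is resolvable when the parent's two haplotypes are fully
    established and the transmitted haplotype is resolved at two or more
    loci; others are skipped and counted in the coverage report. Parent sex
    is carried on every event so paternal/maternal asymmetries are a
    computable output.
    """
    by_phase = {p.id: p for p in phased}
    by_id = dataset.by_id
    pool = _parental_generation_pool(phased, dataset)
    records: list[TransmissionRecord] = []

    for ph in sorted(phased, key=lambda p: p.id):
        ind = by_id[ph.id]
        if not ind.is_offspring:
            continue
        for sex, pid, side in (
            ("dam", ind.dam_id, "maternal"),
            ("sire", ind.sire_id, "paternal"),
        ):
            if pid is None:
                continue
            parent = by_phase[pid]
            transmitted = (
                ph.transmitted_maternal if side == "maternal" else ph.transmitted_paternal
            )
            rec = TransmissionRecord(
                offspring_id=ph.id, parent_id=pid, parent_sex=sex,
                population=ph.population, status=SKIPPED,
                resulting_haplotype=tuple(transmitted),
            )
            parent_ok = hap_complete(parent.hap_maternal) and hap_complete(parent.hap_paternal)
            if not parent_ok or sum(a is not None for a in transmitted) < 2:
                records.append(rec)
                continue
            other_pid = ind.sire_id if sex == "dam" else ind.dam_id
            other_geno = (
                [by_id[other_pid].genotype[n] for n in dataset.panel.names]
                if other_pid is not None
                else None
            )
            expl = explain_transmission(
                (parent.hap_maternal, parent.hap_paternal),
                transmitted,
                dataset.panel,
                offspring_genotype=[ind.genotype[n] for n in dataset.panel.names],
                other_parent_genotype=other_geno,
            )
            rec.ties = expl.ties
            if expl.type == UNEXPLAINED:
                rec.status = UNEXPLAINED
                records.append(rec)
                continue
            new = (
                hap_complete(transmitted)
                and tuple(transmitted) not in pool[ph.population]
            )
            rec.is_new_haplotype = new and expl.type != NONE
            if expl.type == NONE:
                rec.status = NONE
                records.append(rec)
                continue
            rec.status = "events"
            if expl.breakpoints:
                rec.events.append(
                    MeiosisEvent(
                        offspring_id=ph.id, parent_id=pid, parent_sex=sex,
                        type=RECOMBINATION, breakpoints=list(expl.breakpoints),
                        resulting_haplotype=tuple(transmitted),
                        is_new_haplotype=rec.is_new_haplotype,
                    )
                )
            for tract in expl.conversions:
                rec.events.append(
                    MeiosisEvent(
                        offspring_id=ph.id, parent_id=pid, parent_sex=sex,
                        type=CONVERSION, loci=list(tract),
                        resulting_haplotype=tuple(transmitted),
                        is_new_haplotype=rec.is_new_haplotype,
                    )
                )
            for locus, frm, to in expl.indels:
                rec.events.append(
                    MeiosisEvent(
                        offspring_id=ph.id, parent_id=pid, parent_sex=sex,
                        type=INSERTION if to > frm else DELETION,
                        loci=[locus], allele_change=(frm, to),
                        resulting_haplotype=tuple(transmitted),
                        is_new_haplotype=rec.is_new_haplotype,
                    )
                )
            records.append(rec)
    return EventCallSet(records=records, parental_pool=pool)


# ---------------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------------

@dataclass
class EventSummary:
    population: str
    n_offspring: int
    n_meioses: int
    counts: dict[str, int]              # per event type, transmission-level
    recombination_frequency: float      # percent
    conversion_frequency: float
    insertion_frequency: float
    deletion_frequency: float
    n_new_haplotypes: int
    new_haplotype_ratio: float          # percent


def per_meiosis_percent(count: int, n_meioses: int) -> float:
    """100 * count / n_meioses — the per-meiosis event frequency in percent."""
    if n_meioses <= 0:
        raise UndefinedStatisticError("zero meioses")
    return 100.0 * count / n_meioses


def count_meioses(dataset: PopulationDataset, population: str) -> int:
    """Parent-offspring pairs: 2 per full trio, 1 per single-parent pair."""
    n = 0
    for ind in dataset.offspring(population):
        n += (ind.dam_id is not None) + (ind.sire_id is not None)
    return n


def event_frequencies(
    calls: EventCallSet, dataset: PopulationDataset, population: str
) -> EventSummary:
    """Per-population per-meiosis event frequencies (percent)."""
    n_meioses = count_meioses(dataset, population)
    if n_meioses == 0:
        raise UndefinedStatisticError(f"no meioses observable in {population}")
    recs = [r for r in calls.records if r.population == population]
    counts: dict[str, int] = {RECOMBINATION: 0, CONVERSION: 0, INSERTION: 0, DELETION: 0}
    for r in recs:
        present = {e.type for e in r.events}
        for t in present:
            counts[t] += 1
    new_haps = {
        r.resulting_haplotype for r in recs if r.is_new_haplotype
    }
    return EventSummary(
        population=population,
        n_offspring=len(dataset.offspring(population)),
        n_meioses=n_meioses,
        counts=counts,
        recombination_frequency=per_meiosis_percent(counts[RECOMBINATION], n_meioses),
        conversion_frequency=per_meiosis_percent(counts[CONVERSION], n_meioses),
        insertion_frequency=per_meiosis_percent(counts[INSERTION], n_meioses),
        deletion_frequency=per_meiosis_percent(counts[DELETION], n_meioses),
        n_new_haplotypes=len(new_haps),
        new_haplotype_ratio=per_meiosis_percent(len(new_haps), n_meioses),
    )


def new_haplotype_ratio(
    calls: EventCallSet,
    inventory: HaplotypeInventory,
    dataset: PopulationDataset,
    population: str,
) -> float:
    """Percent of meioses yielding a haplotype absent from the parental pool.

    Counts *distinct* fully-resolved offspring haplotypes not present in the
    parental-generation pool, over the number of meioses.
    """
    n_meioses = count_meioses(dataset, population)
    if n_meioses == 0:
        raise UndefinedStatisticError(f"no meioses observable in {population}")
    pool = calls.parental_pool.get(population, set())
    new = {
        r.resulting_haplotype
        for r in calls.records
        if r.population == population
        and hap_complete(r.resulting_haplotype)
        and r.resulting_haplotype not in pool
    }
    return per_meiosis_percent(len(new), n_meioses)
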