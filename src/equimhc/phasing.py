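"""Pedigree-based multi-locus haplotype phasing.

Phase is reconstructed the way a geneticist compares trios by eye, but
algorithmized. Three kinds of evidence are used, in decreasing strength:

1. Mendelian-forced parental-origin assignments within a trio or
   parent-offspring pair (locus by locus);
2. complement closure: a parent's two haplotype alleles at a locus are
   exactly its genotype pair, so establishing one haplotype establishes the
   other;
3. haplotype context: transmissions are matched against the parent's
   accumulating haplotypes, resolving ambiguous loci only when exactly one
   assignment fits, and re-opening locally "forced" assignments that the
   multi-locus context contradicts (the signature of a repeat-unit mutation
   whose allele happens to collide with the other parent's genotype).

Where independent transmissions disagree about a parent's haplotype allele
(which happens only when a rare meiotic event corrupts one of them), the
consensus is taken rather than the first observation; unanimous evidence is
the common case. No statistical or LD-based imputation is ever performed:
loci without evidence stay unknown, and Mendelian-incompatible loci are
flagged as conflicts and handed to event calling, never "fixed".

Iteration order is deterministic (sorted ids), so the result is independent
of input row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .data import Individual, PopulationDataset

Allele = Optional[int]
Hap = tuple[Allele, ...]

RESOLVED = "resolved"
AMBIGUOUS = "ambiguous"
CONFLICT = "conflict"
MISSING = "missing"

#: repeat-unit steps accepted when attributing a context-contradicted allele
#: to a stepwise mutation
_MAX_STEPS = 3


@dataclass
class LocusOrigin:
    """Per-locus parental-origin assignment for one offspring."""

    status: str                 # resolved / ambiguous / conflict / missing
    maternal: Allele = None     # allele transmitted by the dam (if forced)
    paternal: Allele = None     # allele transmitted by the sire (if forced)


@dataclass
class PhasedIndividual:
    """Two ordered haplotypes with per-locus confidence.

    For offspring, ``hap_maternal``/``hap_paternal`` are true parental-origin
    haplotypes (conflict loci excluded — their attributed alleles live in
    ``transmitted_maternal``/``transmitted_paternal`` for event calling).
    For parents phased by propagation from their offspring, the two labels
    are arbitrary phase labels, not parental origins.
    """

    id: str
    population: str
    hap_maternal: Hap
    hap_paternal: Hap
    origin_confidence: tuple[str, ...]
    source: str  # trio / pair / propagated / unphased
    transmitted_maternal: Hap = ()
    transmitted_paternal: Hap = ()


def hap_complete(hap: Sequence[Allele]) -> bool:
    return all(a is not None for a in hap)


def assign_parental_origin(
    offspring: Sequence, dam: Sequence | None, sire: Sequence | None
) -> list[LocusOrigin]:
    """Mendelian parental-origin assignment, locus by locus.

    Inputs are per-locus genotype vectors (sequences of canonical allele
    pairs or ``None``), ordered along the panel; ``dam``/``sire`` may be
    ``None`` when that parent is unknown (always compatible). Returns a
    ``LocusOrigin`` per locus: *resolved* when Mendelian logic forces the
    assignment, *ambiguous* when both assignments are consistent, *conflict*
    when neither is (a candidate event locus — the incompatible side's
    allele is still attributed when the other side is unambiguous).
    """
    L = len(offspring)
    dam = dam if dam is not None else [None] * L
    sire = sire if sire is not None else [None] * L
    out: list[LocusOrigin] = []
    for l in range(L):
        og = offspring[l]
        if og is None:
            out.append(LocusOrigin(MISSING))
            continue
        x, y = og
        gd, gs = dam[l], sire[l]

        def ok_d(a: int) -> bool:
            return gd is None or a in gd

        def ok_s(a: int) -> bool:
            return gs is None or a in gs

        if x == y:
            status = RESOLVED if (ok_d(x) and ok_s(x)) else CONFLICT
            out.append(LocusOrigin(status, maternal=x, paternal=x))
            continue
        p1 = ok_d(x) and ok_s(y)  # x from dam, y from sire
        p2 = ok_d(y) and ok_s(x)
        if p1 and p2:
            out.append(LocusOrigin(AMBIGUOUS))
        elif p1:
            out.append(LocusOrigin(RESOLVED, maternal=x, paternal=y))
        elif p2:
            out.append(LocusOrigin(RESOLVED, maternal=y, paternal=x))
        else:
            # conflict; attribute the mutant side if exactly one pairing has
            # exactly one compatible side
            cands = set()
            if ok_d(x):
                cands.add((x, y))
            if ok_d(y):
                cands.add((y, x))
            if ok_s(y):
                cands.add((x, y))
            if ok_s(x):
                cands.add((y, x))
            if len(cands) == 1:
                m, p = cands.pop()
                out.append(LocusOrigin(CONFLICT, maternal=m, paternal=p))
            else:
                out.append(LocusOrigin(CONFLICT))
    return out


def phase_trio(
    offspring: Sequence, dam: Sequence | None, sire: Sequence | None
) -> list[LocusOrigin]:
    """Single-trio phase: Mendelian-forced assignments only (no pool)."""
    return assign_parental_origin(offspring, dam, sire)


# ---------------------------------------------------------------------------
# parent phase (two complement-closed partial haplotypes)
# ---------------------------------------------------------------------------

class _Phase:
    """Two partial haplotypes (A, B) for one individual.

    At every typed locus the two haplotype alleles are a permutation of the
    genotype pair, so fixing A fixes B there too (complement closure).
    Homozygous loci are known from the start.
    """

    __slots__ = ("genotype", "A", "B")

    def __init__(self, genotype):
        self.genotype = genotype
        L = len(genotype)
        self.A: list[Allele] = [None] * L
        self.B: list[Allele] = [None] * L
        for l, g in enumerate(genotype):
            if g is not None and g[0] == g[1]:
                self.A[l] = self.B[l] = g[0]

    def het(self, l: int) -> bool:
        g = self.genotype[l]
        return g is not None and g[0] != g[1]

    def close(self) -> None:
        for l, g in enumerate(self.genotype):
            if g is None:
                continue
            if self.A[l] is not None and self.B[l] is None:
                self.B[l] = g[1] if self.A[l] == g[0] else g[0]
            elif self.B[l] is not None and self.A[l] is None:
                self.A[l] = g[1] if self.B[l] == g[0] else g[0]

    def set_hap(self, which: str, l: int, allele: int) -> None:
        (self.A if which == "A" else self.B)[l] = allele

    def relation(self, t: Sequence[Allele], which: str) -> tuple[int, int]:
        """(het-locus agreements, conflicts) of a partial hap vs A or B."""
        hap = self.A if which == "A" else self.B
        agrees = conflicts = 0
        for l, a in enumerate(t):
            if a is None or hap[l] is None:
                continue
            if a == hap[l]:
                if self.het(l):
                    agrees += 1
            else:
                conflicts += 1
        return agrees, conflicts

    def classify(self, t: Sequence[Allele]) -> str | None:
        """Which haplotype a transmitted partial must be: 'A', 'B',
        'anomalous' (fits neither — event candidate) or None (not forced)."""
        ag_a, cf_a = self.relation(t, "A")
        ag_b, cf_b = self.relation(t, "B")
        fits_a = ag_a > 0 and cf_a == 0
        fits_b = ag_b > 0 and cf_b == 0
        if cf_a and cf_b:
            return "anomalous"
        if fits_a and not fits_b:
            return "A"
        if fits_b and not fits_a:
            return "B"
        if cf_a and not cf_b:
            return "B"
        if cf_b and not cf_a:
            return "A"
        return None

    def has_het_info(self) -> bool:
        return any(self.A[l] is not None and self.het(l) for l in range(len(self.A)))

    def state(self):
        return (tuple(self.A), tuple(self.B))


# ---------------------------------------------------------------------------
# population driver
# ---------------------------------------------------------------------------

def _geno_vector(ind: Individual, names):
    return [ind.genotype[n] for n in names]


class _Phaser:
    def __init__(self, dataset: PopulationDataset):
        self.dataset = dataset
        self.names = dataset.panel.names
        self.L = len(self.names)
        self.by_id = dataset.by_id
        self.ids = sorted(self.by_id)
        self.geno = {i: _geno_vector(self.by_id[i], self.names) for i in self.ids}
        self.offspring_ids = sorted(
            i for i in self.ids if self.by_id[i].is_offspring
        )
        self.children: dict[str, list[tuple[str, str]]] = {}
        for oid in self.offspring_ids:
            ind = self.by_id[oid]
            if ind.dam_id:
                self.children.setdefault(ind.dam_id, []).append((oid, "maternal"))
            if ind.sire_id:
                self.children.setdefault(ind.sire_id, []).append((oid, "paternal"))
        for v in self.children.values():
            v.sort()
        self.overrides: dict[tuple[str, int], LocusOrigin] = {}
        self.origins: dict[str, list[LocusOrigin]] = {}
        self.phases: dict[str, _Phase] = {}

    # -- origins ------------------------------------------------------------

    def _initial_origins(self) -> None:
        self.origins = {}
        for oid in self.offspring_ids:
            ind = self.by_id[oid]
            dam = self.geno[ind.dam_id] if ind.dam_id else None
            sire = self.geno[ind.sire_id] if ind.sire_id else None
            orig = assign_parental_origin(self.geno[oid], dam, sire)
            for l in range(self.L):
                if (oid, l) in self.overrides:
                    orig[l] = self.overrides[(oid, l)]
            self.origins[oid] = orig

    def transmitted(self, oid: str, side: str) -> list[Allele]:
        key = "maternal" if side == "maternal" else "paternal"
        return [
            getattr(o, key) if o.status == RESOLVED else None
            for o in self.origins[oid]
        ]

    # -- parent phase consensus ---------------------------------------------

    def _reference(self, pid: str, prev: _Phase, trans) -> _Phase:
        """Classification reference: previous phase, or a trial anchor chosen
        as the transmission most consistent with its siblings."""
        if prev.has_het_info():
            return prev
        best = None
        for o, s, t in trans:
            if not any(a is not None for a in t):
                continue
            trial = _Phase(self.geno[pid])
            for l, a in enumerate(t):
                if a is not None and trial.A[l] is None:
                    trial.A[l] = a
            trial.close()
            score = sum(
                1
                for o2, s2, t2 in trans
                if (o2, s2) != (o, s) and trial.classify(t2) != "anomalous"
            )
            key = (-score, o, s)
            if best is None or key < best[0]:
                best = (key, trial)
        return best[1] if best else prev

    def _rebuild_phases(self, prev: dict[str, _Phase]) -> dict[str, _Phase]:
        phases: dict[str, _Phase] = {}
        for iid in self.ids:
            ph = _Phase(self.geno[iid])
            # an offspring's own phase is pinned by its trio assignments
            if iid in self.origins:
                for l, o in enumerate(self.origins[iid]):
                    if o.status == RESOLVED:
                        if ph.A[l] is None:
                            ph.A[l] = o.maternal
                        if ph.B[l] is None:
                            ph.B[l] = o.paternal
                ph.close()
            phases[iid] = ph

        for pid in sorted(self.children):
            ph = phases[pid]
            trans = [
                (oid, side, self.transmitted(oid, side))
                for oid, side in self.children[pid]
            ]
            ref = self._reference(pid, prev[pid], trans)
            votes: dict[tuple[str, int], dict[int, int]] = {}
            for oid, side, t in trans:
                which = ref.classify(t)
                if which not in ("A", "B"):
                    continue
                for l, a in enumerate(t):
                    if a is None:
                        continue
                    votes.setdefault((which, l), {}).setdefault(a, 0)
                    votes[(which, l)][a] += 1
            for (which, l), tally in sorted(votes.items()):
                hap = ph.A if which == "A" else ph.B
                if hap[l] is not None:  # pinned by own trio or homozygosity
                    continue
                ranked = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
                if len(ranked) == 1 or ranked[0][1] > ranked[1][1]:
                    hap[l] = ranked[0][0]
            ph.close()
        return phases

    # -- ambiguity resolution against established haplotypes -----------------

    def _pool_match(self) -> bool:
        changed = False
        for oid in self.offspring_ids:
            ind = self.by_id[oid]
            orig = self.origins[oid]
            for l in range(self.L):
                if orig[l].status != AMBIGUOUS:
                    continue
                x, y = self.geno[oid][l]
                proposals = set()
                for side, pid in (("maternal", ind.dam_id), ("paternal", ind.sire_id)):
                    if pid is None:
                        continue
                    ph = self.phases[pid]
                    t = self.transmitted(oid, side)
                    t[l] = None
                    which = ph.classify(t)
                    if which not in ("A", "B"):
                        continue
                    hap = ph.A if which == "A" else ph.B
                    if hap[l] is None:
                        continue
                    if hap[l] == x:
                        proposals.add((x, y) if side == "maternal" else (y, x))
                    elif hap[l] == y:
                        proposals.add((y, x) if side == "maternal" else (x, y))
                if len(proposals) == 1:
                    m, p = proposals.pop()
                    orig[l] = LocusOrigin(RESOLVED, maternal=m, paternal=p)
                    changed = True
        return changed

    # -- context corrections -------------------------------------------------

    def _context_haps(self, pid: str, oid: str, side: str, l: int):
        """(matched hap, homolog hap) of a transmission, judged without locus l."""
        ph = self.phases[pid]
        t = self.transmitted(oid, side)
        t[l] = None
        ag_a, cf_a = ph.relation(t, "A")
        ag_b, cf_b = ph.relation(t, "B")
        fits_a = ag_a >= 2 and cf_a == 0
        fits_b = ag_b >= 2 and cf_b == 0
        if fits_a and not fits_b:
            return ph.A, ph.B
        if fits_b and not fits_a:
            return ph.B, ph.A
        return None, None

    def _side_cost(self, allele: int, pid: str | None, oid: str, side: str, l: int):
        """(cost, flag) of one parent having transmitted ``allele`` at l.

        cost 0: exact or indistinguishable; cost 1: a single event —
        conversion (allele equals the homologous haplotype's allele) or a
        stepwise repeat-unit mutation; inf: inexplicable. The flag says
        whether the side is a Mendelian conflict ("mutant") so the locus can
        be handed to event calling.
        """
        if pid is None:
            return 0.0, "unknown"
        g = self.geno[pid][l]
        unit = self.dataset.panel[l].repeat_unit

        def small_step(d: int) -> bool:
            return d != 0 and d % unit == 0 and abs(d) // unit <= _MAX_STEPS

        if g is None:
            return 0.0, "unknown"
        if allele in g:
            hap, homolog = self._context_haps(pid, oid, side, l)
            if hap is None or hap[l] is None:
                return 0.0, "unplaced"
            if hap[l] == allele:
                return 0.0, "exact"
            if homolog[l] == allele:
                return 1.0, "conversion"
            return 1.0, "other"
        # Mendelian conflict: only a stepwise mutation can explain it
        hap, _ = self._context_haps(pid, oid, side, l)
        if hap is not None and hap[l] is not None:
            if small_step(allele - hap[l]):
                return 1.0, "mutant"
            return float("inf"), "mutant"
        if any(small_step(allele - a) for a in g):
            return 1.0, "mutant"
        return float("inf"), "mutant"

    def _detect_corrections(self) -> dict[tuple[str, int], LocusOrigin]:
        """Re-attribute offspring loci that haplotype context refutes.

        A repeat-unit mutation whose allele collides with the other parent's
        genotype produces a Mendelian-forced but wrong assignment (or an
        unattributable conflict). Comparing the two possible attributions by
        their total context cost — exact match 0, conversion or stepwise
        mutation 1, inexplicable inf — recovers the one a geneticist would
        choose from the multi-locus context. Re-attribution happens only
        when the alternative is strictly cheaper, or when the current state
        carries no attribution at all.
        """
        corrections: dict[tuple[str, int], LocusOrigin] = {}
        for oid in self.offspring_ids:
            ind = self.by_id[oid]
            orig = self.origins[oid]
            for l in range(self.L):
                if (oid, l) in self.overrides:
                    continue
                g = self.geno[oid][l]
                if g is None or g[0] == g[1] or orig[l].status == MISSING:
                    continue
                x, y = g
                cands = []
                for mat, pat in ((x, y), (y, x)):
                    cd, fd = self._side_cost(mat, ind.dam_id, oid, "maternal", l)
                    cs, fs = self._side_cost(pat, ind.sire_id, oid, "paternal", l)
                    cands.append((cd + cs, mat, pat, fd, fs))
                cands.sort(key=lambda c: (c[0], c[1]))
                best = cands[0]
                if best[0] == float("inf"):
                    continue
                cur = orig[l]
                if cur.maternal is not None:
                    cur_cost = next(
                        c[0] for c in cands if c[1] == cur.maternal
                    )
                    better = best[0] < cur_cost and best[1] != cur.maternal
                elif cands[0][0] < cands[1][0]:
                    better = True
                else:
                    # tied: attribute only unexplained conflicts (the event
                    # count is the same either way; the side is uncertain)
                    better = cur.status == CONFLICT and best[0] < float("inf")
                if not better:
                    continue
                _, mat, pat, fd, fs = best
                status = CONFLICT if "mutant" in (fd, fs) else RESOLVED
                if status == RESOLVED and cur.status == RESOLVED and cur.maternal == mat:
                    continue
                corrections[(oid, l)] = LocusOrigin(status, maternal=mat, paternal=pat)
        return corrections

    # -- driver ---------------------------------------------------------------

    def run(self, max_rounds: int = 4) -> None:
        for _ in range(max_rounds):
            self._initial_origins()
            self.phases = {i: _Phase(self.geno[i]) for i in self.ids}
            for _ in range(self.L + 10):
                new_phases = self._rebuild_phases(self.phases)
                phase_changed = any(
                    new_phases[i].state() != self.phases[i].state() for i in self.ids
                )
                self.phases = new_phases
                pool_changed = self._pool_match()
                if not phase_changed and not pool_changed:
                    break
            corrections = self._detect_corrections()
            new = {k: v for k, v in corrections.items() if k not in self.overrides}
            if not new:
                break
            self.overrides.update(new)

    def results(self) -> list[PhasedIndividual]:
        out: list[PhasedIndividual] = []
        for iid in self.ids:
            ind = self.by_id[iid]
            if ind.is_offspring:
                orig = self.origins[iid]
                hm = tuple(o.maternal if o.status == RESOLVED else None for o in orig)
                hp = tuple(o.paternal if o.status == RESOLVED else None for o in orig)
                tm = tuple(
                    o.maternal if o.status in (RESOLVED, CONFLICT) else None
                    for o in orig
                )
                tp = tuple(
                    o.paternal if o.status in (RESOLVED, CONFLICT) else None
                    for o in orig
                )
                out.append(
                    PhasedIndividual(
                        id=iid,
                        population=ind.population,
                        hap_maternal=hm,
                        hap_paternal=hp,
                        origin_confidence=tuple(o.status for o in orig),
                        source="trio" if (ind.dam_id and ind.sire_id) else "pair",
                        transmitted_maternal=tm,
                        transmitted_paternal=tp,
                    )
                )
            else:
                ph = self.phases[iid]
                conf = tuple(
                    RESOLVED if (ph.A[l] is not None and ph.B[l] is not None)
                    else (MISSING if self.geno[iid][l] is None else AMBIGUOUS)
                    for l in range(self.L)
                )
                out.append(
                    PhasedIndividual(
                        id=iid,
                        population=ind.population,
                        hap_maternal=tuple(ph.A),
                        hap_paternal=tuple(ph.B),
                        origin_confidence=conf,
                        source="propagated" if iid in self.children else "unphased",
                        transmitted_maternal=tuple([None] * self.L),
                        transmitted_paternal=tuple([None] * self.L),
                    )
                )
        return out


def phase_population(dataset: PopulationDataset) -> list[PhasedIndividual]:
    """Phase every individual by iterative constraint propagation.

    Offspring are phased from trios/pairs; parents accumulate phase from
    the haplotypes they transmitted (consensus across offspring); remaining
    ambiguities are re-resolved against each parent's established
    haplotypes, and locally forced assignments contradicted by haplotype
    context are re-opened. Runs to a fixpoint; deterministic and
    independent of input row order.
    """
    phaser = _Phaser(dataset)
    phaser.run()
    return phaser.results()


# ---------------------------------------------------------------------------
# haplotype inventory
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeInventory:
    """Distinct fully-resolved haplotypes per population with copy counts.

    Haplotype identity requires every panel locus resolved; haplotypes with
    any unknown locus are never counted as distinct, only tallied as
    unresolved.
    """

    per_population: dict[str, dict[Hap, int]]
    unresolved: dict[str, int]

    def totals(self) -> dict[str, int]:
        return {pop: len(haps) for pop, haps in self.per_population.items()}


def haplotype_inventory(
    phased: list[PhasedIndividual], dataset: PopulationDataset
) -> HaplotypeInventory:
    per_pop: dict[str, dict[Hap, int]] = {p: {} for p in dataset.populations}
    unresolved: dict[str, int] = {p: 0 for p in dataset.populations}
    for ph in phased:
        for hap in (ph.hap_maternal, ph.hap_paternal):
            if hap_complete(hap):
                d = per_pop[ph.population]
                d[hap] = d.get(hap, 0) + 1
            else:
                unresolved[ph.population] += 1
    return HaplotypeInventory(per_population=per_pop, unresolved=unresolved)


def shared_haplotypes(
    inventory: HaplotypeInventory, pop_a: str, pop_b: str
) -> list[Hap]:
    """Exact intersection of two populations' fully-resolved haplotype sets."""
    a = set(inventory.per_population.get(pop_a, ()))
    b = set(inventory.per_population.get(pop_b, ()))
    return sorted(a & b)
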