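"""Genotype/pedigree containers, file I/O and dataset validation.

Genotypes are unordered pairs of fragment sizes in bp; allele identity is
fragment length (no sequence-level identity). A locus with either allele
missing is treated as wholly missing, and individuals missing a locus are
dropped from that locus's statistics only (pairwise deletion).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .panel import LocusPanel

GenotypePair = tuple[int, int]


class FormatError(ValueError):
    """Malformed input file (unknown column, bad token, wrong layout)."""


class ValidationError(ValueError):
    """Inconsistent dataset (duplicate id, dangling reference, cycle)."""


class UndefinedStatisticError(ValueError):
    """A statistic was requested on data that cannot define it."""


def canonical_pair(a: int, b: int) -> GenotypePair:
    """Allele pair as a sorted tuple; pair order carries no meaning."""
    if a <= 0 or b <= 0:
        raise ValueError("allele sizes must be positive")
    return (a, b) if a <= b else (b, a)


@dataclass
class Individual:
    """One diploid individual with its genotype vector over a panel.

    ``genotype`` maps locus name -> canonical (sorted) allele pair or None
    for a missing locus. An individual is an *offspring* iff at least one
    parent id is present.
    """

    id: str
    population: str
    genotype: dict[str, GenotypePair | None]
    sire_id: str | None = None
    dam_id: str | None = None

    @property
    def is_offspring(self) -> bool:
        return self.sire_id is not None or self.dam_id is not None


@dataclass
class PopulationDataset:
    """Panel + individuals; the universal input of every analysis stage."""

    panel: LocusPanel
    individuals: list[Individual]

    def __post_init__(self) -> None:
        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate individual id(s): {dupes}")
        names = set(self.panel.names)
        for ind in self.individuals:
            if set(ind.genotype) != names:
                raise ValidationError(
                    f"individual {ind.id!r}: genotype vector does not cover the panel"
                )
        self._check_parent_links()

    def _check_parent_links(self) -> None:
        by_id = self.by_id
        for ind in self.individuals:
            for pid in (ind.sire_id, ind.dam_id):
                if pid is not None and pid not in by_id:
                    raise ValidationError(
                        f"individual {ind.id!r} references unknown parent {pid!r}"
                    )
        # no individual may be its own ancestor
        def ancestors(start: str) -> None:
            seen = set()
            stack = [start]
            while stack:
                cur = stack.pop()
                ind = by_id[cur]
                for pid in (ind.sire_id, ind.dam_id):
                    if pid is None:
                        continue
                    if pid == start:
                        raise ValidationError(f"pedigree cycle involving {start!r}")
                    if pid not in seen:
                        seen.add(pid)
                        stack.append(pid)

        for ind in self.individuals:
            ancestors(ind.id)

    @property
    def by_id(self) -> dict[str, Individual]:
        return {ind.id: ind for ind in self.individuals}

    @property
    def populations(self) -> list[str]:
        seen: list[str] = []
        for ind in self.individuals:
            if ind.population not in seen:
                seen.append(ind.population)
        return seen

    def subset(self, population: str | Iterable[str] | None = None) -> list[Individual]:
        if population is None:
            return list(self.individuals)
        pops = {population} if isinstance(population, str) else set(population)
        return [ind for ind in self.individuals if ind.population in pops]

    def offspring(self, population: str | None = None) -> list[Individual]:
        return [ind for ind in self.subset(population) if ind.is_offspring]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for ind in self.individuals:
            row: dict[str, object] = {"id": ind.id, "population": ind.population}
            for name in self.panel.names:
                g = ind.genotype[name]
                row[f"{name}.1"] = g[0] if g else ""
                row[f"{name}.2"] = g[1] if g else ""
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_genotype_table(path, panel: LocusPanel) -> PopulationDataset:
    """Read a wide genotype CSV (columns id, population, then <locus>.1/.2).

    Missing alleles may be coded as an empty cell or ``0``; if either allele
    of a pair is missing the whole locus is missing. Allele pairs are
    canonicalized (sorted), so column order within a pair carries no meaning.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    cols = list(df.columns)
    if "id" not in cols or "population" not in cols:
        raise FormatError("genotype table must have 'id' and 'population' columns")
    wanted = {f"{n}.{k}" for n in panel.names for k in (1, 2)}
    extra = [c for c in cols if c not in wanted and c not in ("id", "population")]
    if extra:
        raise FormatError(f"unknown locus column(s): {extra}")
    missing_cols = sorted(wanted - set(cols))
    if missing_cols:
        raise FormatError(f"missing locus column(s): {missing_cols}")

    individuals: list[Individual] = []
    for rownum, rec in enumerate(df.to_dict("records"), start=2):  # 1 header line
        geno: dict[str, GenotypePair | None] = {}
        for name in panel.names:
            raw = [str(rec[f"{name}.{k}"]).strip() for k in (1, 2)]
            vals: list[int] = []
            for tok in raw:
                if tok in ("", "0", "0.0"):
                    vals.append(0)
                    continue
                try:
                    v = int(float(tok)) if float(tok) == int(float(tok)) else None
                except ValueError:
                    v = None
                if v is None:
                    raise FormatError(
                        f"row {rownum}: non-integer allele {tok!r} at locus {name}"
                    )
                vals.append(v)
            if 0 in vals:
                geno[name] = None
            else:
                geno[name] = canonical_pair(vals[0], vals[1])
        individuals.append(
            Individual(id=str(rec["id"]).strip(), population=str(rec["population"]).strip(),
                       genotype=geno)
        )
    return PopulationDataset(panel=panel, individuals=individuals)


def read_pedigree(path, dataset: PopulationDataset) -> PopulationDataset:
    """Attach sire/dam links from a pedigree CSV (columns id, sire, dam).

    Blank parent cells mean unknown. Every id must already exist in the
    dataset; cycles (including self-parenting) are rejected.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    for col in ("id", "sire", "dam"):
        if col not in df.columns:
            raise FormatError("pedigree must have columns id, sire, dam")
    by_id = dataset.by_id
    for rownum, rec in enumerate(df.to_dict("records"), start=2):
        iid = str(rec["id"]).strip()
        if iid not in by_id:
            raise ValidationError(f"row {rownum}: pedigree id {iid!r} absent from dataset")
        sire = str(rec["sire"]).strip() or None
        dam = str(rec["dam"]).strip() or None
        for pid in (sire, dam):
            if pid is not None and pid not in by_id:
                raise ValidationError(
                    f"row {rownum}: parent {pid!r} of {iid!r} absent from dataset"
                )
        by_id[iid].sire_id = sire
        by_id[iid].dam_id = dam
    # revalidate links/cycles
    dataset._check_parent_links()
    return dataset


# ---------------------------------------------------------------------------
# Genepop interoperability
# ---------------------------------------------------------------------------

def _allele_codes(dataset: PopulationDataset) -> dict[str, dict[int, int]]:
    """Rank-based 3-digit codes per locus: sizes sorted ascending, from 001."""
    codes: dict[str, dict[int, int]] = {}
    for name in dataset.panel.names:
        sizes = sorted(
            {a for ind in dataset.individuals
             for a in (ind.genotype[name] or ())}
        )
        if len(sizes) > 999:
            raise FormatError(f"locus {name}: more than 999 distinct alleles")
        codes[name] = {size: i + 1 for i, size in enumerate(sizes)}
    return codes


def write_genepop(dataset: PopulationDataset, path, title: str = "equimhc export") -> None:
    """Write Genepop 4.x text with rank-coded 3-digit alleles.

    Each observed allele size is mapped per locus to a 3-digit code (sorted
    ascending, starting 001); a sidecar JSON next to ``path`` records the
    code -> bp map so the export round-trips losslessly.
    """
    codes = _allele_codes(dataset)
    lines = [title]
    lines.extend(dataset.panel.names)
    for pop in dataset.populations:
        lines.append("Pop")
        for ind in dataset.subset(pop):
            toks = []
            for name in dataset.panel.names:
                g = ind.genotype[name]
                if g is None:
                    toks.append("000000")
                else:
                    toks.append(f"{codes[name][g[0]]:03d}{codes[name][g[1]]:03d}")
            lines.append(f"{ind.id} ,  " + " ".join(toks))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    sidecar = {
        "populations": dataset.populations,
        "codes": {
            name: {str(code): size for size, code in table.items()}
            for name, table in codes.items()
        },
    }
    with open(str(path) + ".codes.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_genepop(path, panel: LocusPanel) -> PopulationDataset:
    """Companion reader for :func:`write_genepop` output (requires sidecar)."""
    with open(str(path) + ".codes.json") as fh:
        sidecar = json.load(fh)
    decode = {
        name: {int(c): int(size) for c, size in table.items()}
        for name, table in sidecar["codes"].items()
    }
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    n = len(panel)
    if lines[1 : 1 + n] != panel.names:
        raise FormatError("Genepop locus list does not match the panel")
    individuals: list[Individual] = []
    pop_idx = -1
    pops = sidecar["populations"]
    for ln in lines[1 + n :]:
        if not ln.strip():
            continue
        if ln.strip().lower() == "pop":
            pop_idx += 1
            continue
        ident, _, rest = ln.partition(",")
        toks = rest.split()
        if len(toks) != n:
            raise FormatError(f"individual {ident.strip()!r}: expected {n} locus fields")
        geno: dict[str, GenotypePair | None] = {}
        for name, tok in zip(panel.names, toks):
            c1, c2 = int(tok[:3]), int(tok[3:])
            if c1 == 0 or c2 == 0:
                geno[name] = None
            else:
                geno[name] = canonical_pair(decode[name][c1], decode[name][c2])
        individuals.append(
            Individual(id=ident.strip(), population=pops[pop_idx], genotype=geno)
        )
    return PopulationDataset(panel=panel, individuals=individuals)


# ---------------------------------------------------------------------------
# validation report
# ---------------------------------------------------------------------------

@dataclass
class MendelianIncompatibility:
    """Offspring shares no allele with a typed parent at a locus.

    These are *reported, not removed*: single-locus incompatibilities are the
    raw material of event calling (candidate repeat-unit insertions/deletions
    or conversions), not necessarily errors.
    """

    offspring_id: str
    parent_id: str
    parent_role: str  # "dam" | "sire"
    locus: str


@dataclass
class ValidationReport:
    n_individuals: int
    n_offspring: int
    missingness: dict[str, float]  # locus -> fraction missing
    incompatibilities: list[MendelianIncompatibility]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "offspring": x.offspring_id,
                    "parent": x.parent_id,
                    "role": x.parent_role,
                    "locus": x.locus,
                }
                for x in self.incompatibilities
            ]
        )

    def to_json(self, path) -> None:
        payload = {
            "n_individuals": self.n_individuals,
            "n_offspring": self.n_offspring,
            "missingness": self.missingness,
            "incompatibilities": [
                {
                    "offspring": x.offspring_id,
                    "parent": x.parent_id,
                    "role": x.parent_role,
                    "locus": x.locus,
                }
                for x in self.incompatibilities
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def mendelian_compatible(off: GenotypePair, parent: GenotypePair) -> bool:
    """True iff the offspring shares at least one allele with the parent."""
    return bool(set(off) & set(parent))


def validate_dataset(dataset: PopulationDataset) -> ValidationReport:
    """Report-only checks: per-locus missingness and Mendelian incompatibilities."""
    n = len(dataset.individuals)
    missing = {
        name: (sum(1 for ind in dataset.individuals if ind.genotype[name] is None) / n
               if n else 0.0)
        for name in dataset.panel.names
    }
    incompat: list[MendelianIncompatibility] = []
    by_id = dataset.by_id
    for ind in dataset.individuals:
        for role, pid in (("dam", ind.dam_id), ("sire", ind.sire_id)):
            if pid is None:
                continue
            parent = by_id[pid]
            for name in dataset.panel.names:
                og, pg = ind.genotype[name], parent.genotype[name]
                if og is None or pg is None:
                    continue
                if not mendelian_compatible(og, pg):
                    incompat.append(
                        MendelianIncompatibility(ind.id, pid, role, name)
                    )
    return ValidationReport(
        n_individuals=n,
        n_offspring=len(dataset.offspring()),
        missingness=missing,
        incompatibilities=incompat,
    )
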