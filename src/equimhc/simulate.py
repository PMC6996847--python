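"""Forward pedigree simulator with planted meiotic events and a truth log.

Emulates the structure of a multi-population MHC-microsatellite study:
founder dams/sires per population carry haplotypes drawn from a finite
per-population founder pool (with optional cross-population sharing),
offspring are produced by simulated meioses in which crossovers, short gene
conversions and single-repeat-unit indels are planted at configured rates,
and every draw is logged so planted events can be replayed and recovered.

Randomness: a single root seed; each meiosis uses its own counter-based
substream keyed by (population, offspring, parent side), so adding offspring
never perturbs earlier draws and identical seed + config gives byte-identical
outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .data import Individual, PopulationDataset, canonical_pair
from .panel import LocusPanel, default_panel

Hap = tuple[int, ...]


@dataclass
class PopulationConfig:
    name: str
    n_founder_dams: int
    n_founder_sires: int
    n_offspring: int


@dataclass
class SimConfig:
    """Study-design parameters for the simulator.

    Defaults (see :func:`study_config`) mirror a three-population design:
    one large draft-horse-like population and two related smaller ones, 11
    loci with 5-14 founder alleles each, family trios, and rare meiotic
    events.

    Parameters
    ----------
    crossover_prob : float
        Per-interval, per-meiosis switch probability (10 intervals on the
        default panel, so the per-meiosis crossover expectation is about
        10x this value).
    conversion_prob : float
        Per-meiosis probability of one 1-2 locus internal conversion tract.
    indel_prob : float
        Per-locus, per-meiosis probability of a +/- one-repeat-unit shift.
    sharing : mapping (popA, popB) -> fraction
        Fraction of the second population's founder haplotype pool copied
        from the first population's pool.
    founder_pool_factor : float
        Founder haplotype pool size = max(4, round(factor * n_founders)).
    """

    panel: LocusPanel
    populations: list[PopulationConfig]
    founder_allele_counts: dict[str, int]
    crossover_prob: float = 0.007
    conversion_prob: float = 0.02
    indel_prob: float = 0.0018
    sharing: dict[tuple[str, str], float] = field(default_factory=dict)
    founder_pool_factor: float = 1.6
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.crossover_prob, self.conversion_prob, self.indel_prob,
                  *self.sharing.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        for name, c in self.founder_allele_counts.items():
            if c < 2:
                raise ValueError(f"founder allele count at {name} must be >= 2")
        for pc in self.populations:
            if pc.n_founder_dams + pc.n_founder_sires < 2:
                raise ValueError(f"{pc.name}: need >= 2 founders")


#: per-locus founder allele counts matching the observed 5-14 range
_STUDY_ALLELE_COUNTS = {
    "COR110": 12, "UMN-JH38": 5, "TAMU30593": 10, "ABGe9019": 13, "UMNe65": 10,
    "ABGe9030": 7, "TKY3324": 11, "COR112": 10, "COR113": 14, "UM011": 14,
    "COR114": 8,
}


def study_config(seed: int = 0, panel: LocusPanel | None = None) -> SimConfig:
    """The default three-population study design."""
    panel = panel or default_panel()
    return SimConfig(
        panel=panel,
        populations=[
            PopulationConfig("Pop1", n_founder_dams=49, n_founder_sires=8, n_offspring=43),
            PopulationConfig("Pop2", n_founder_dams=16, n_founder_sires=4, n_offspring=12),
            PopulationConfig("Pop3", n_founder_dams=19, n_founder_sires=4, n_offspring=15),
        ],
        founder_allele_counts=dict(_STUDY_ALLELE_COUNTS),
        sharing={("Pop2", "Pop3"): 0.10},
        seed=seed,
    )


@dataclass
class TruthMeiosis:
    offspring_id: str
    parent_id: str
    parent_sex: str           # dam | sire
    start_haplotype: int      # 0 or 1
    events: list[dict]
    transmitted: Hap
    effectual: bool           # transmitted differs from both parental haps


@dataclass
class TruthLog:
    """Ground truth: founder phases and every planted event per meiosis."""

    founders: dict[str, tuple[Hap, Hap]]
    meioses: list[TruthMeiosis]
    pools: dict[str, list[Hap]]

    def to_json(self, path) -> None:
        payload = {
            "founders": {k: [list(a), list(b)] for k, (a, b) in self.founders.items()},
            "pools": {k: [list(h) for h in v] for k, v in self.pools.items()},
            "meioses": [
                {
                    "offspring_id": m.offspring_id,
                    "parent_id": m.parent_id,
                    "parent_sex": m.parent_sex,
                    "start_haplotype": m.start_haplotype,
                    "events": m.events,
                    "transmitted": list(m.transmitted),
                    "effectual": m.effectual,
                }
                for m in self.meioses
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# founders
# ---------------------------------------------------------------------------

def _allele_lattices(config: SimConfig, rng: np.random.Generator) -> dict[str, list[int]]:
    """Distinct allele sizes per locus on the repeat-unit lattice in range."""
    out: dict[str, list[int]] = {}
    for locus in config.panel:
        lo, hi = locus.size_range or (200, 200 + 2 * locus.repeat_unit * 24)
        lattice = list(range(lo, hi + 1, locus.repeat_unit))
        k = config.founder_allele_counts[locus.name]
        if k > len(lattice):
            raise ValueError(f"{locus.name}: size_range too narrow for {k} alleles")
        sizes = rng.choice(len(lattice), size=k, replace=False)
        out[locus.name] = sorted(lattice[i] for i in sizes)
    return out


def sample_founders(
    config: SimConfig,
) -> tuple[list[Individual], dict[str, list[Hap]], dict[str, tuple[Hap, Hap]]]:
    """Draw founder haplotype pools and founder individuals under HWE.

    Each population gets its own finite haplotype pool (distinct across
    populations except for configured sharing); each founder receives two
    independent uniform draws from its population's pool, i.e. random union
    of gametes. Deterministic given the config seed.
    """
    rng = np.random.default_rng([config.seed, 0xF0])
    lattices = _allele_lattices(config, rng)
    names = config.panel.names

    pools: dict[str, list[Hap]] = {}
    used: set[Hap] = set()
    for pc in config.populations:
        n_founders = pc.n_founder_dams + pc.n_founder_sires
        pool_size = max(4, round(config.founder_pool_factor * n_founders))
        # population-specific allele frequencies induce differentiation
        weights = {
            name: rng.dirichlet(np.ones(len(lattices[name]))) for name in names
        }
        pool: list[Hap] = []
        guard = 0
        while len(pool) < pool_size:
            hap = tuple(
                int(np.array(lattices[name])[rng.choice(len(lattices[name]),
                                                        p=weights[name])])
                for name in names
            )
            guard += 1
            if guard > 100 * pool_size:
                raise RuntimeError("could not draw enough distinct founder haplotypes")
            if hap in used:
                continue
            used.add(hap)
            pool.append(hap)
        pools[pc.name] = pool

    for (src, dst), frac in sorted(config.sharing.items()):
        if src not in pools or dst not in pools:
            raise ValueError(f"sharing refers to unknown population pair {(src, dst)}")
        k = int(round(frac * min(len(pools[src]), len(pools[dst]))))
        for i in range(k):
            pools[dst][i] = pools[src][i]

    founders: list[Individual] = []
    phases: dict[str, tuple[Hap, Hap]] = {}
    for pc in config.populations:
        pool = pools[pc.name]
        roles = [("D", pc.n_founder_dams), ("S", pc.n_founder_sires)]
        for tag, count in roles:
            for i in range(count):
                iid = f"{pc.name}_{tag}{i + 1:03d}"
                h1 = pool[int(rng.integers(len(pool)))]
                h2 = pool[int(rng.integers(len(pool)))]
                phases[iid] = (h1, h2)
                geno = {
                    name: canonical_pair(h1[j], h2[j])
                    for j, name in enumerate(names)
                }
                founders.append(Individual(id=iid, population=pc.name, genotype=geno))
    return founders, pools, phases


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def simulate_meiosis(
    haps: tuple[Hap, Hap],
    panel: LocusPanel,
    crossover_prob,
    conversion_prob: float,
    indel_prob: float,
    rng: np.random.Generator,
) -> tuple[Hap, list[dict], int]:
    """One gamete: start haplotype by fair coin, per-interval switching,
    optional 1-2 locus internal conversion, per-locus repeat-unit indels.

    Returns (transmitted haplotype, planted events, start haplotype index).
    """
    L = len(panel)
    names = panel.names
    if np.isscalar(crossover_prob):
        xprobs = [float(crossover_prob)] * (L - 1)
    else:
        xprobs = list(crossover_prob)
    start = int(rng.integers(2))
    cur = start
    source = [start] * L
    events: list[dict] = []
    for i in range(1, L):
        if rng.random() < xprobs[i - 1]:
            cur ^= 1
            events.append({"type": "crossover", "interval": [names[i - 1], names[i]]})
        source[i] = cur
    transmitted = [haps[source[i]][i] for i in range(L)]

    if L >= 3 and rng.random() < conversion_prob:
        tract_len = int(rng.integers(1, 3))  # 1 or 2 loci
        tract_len = min(tract_len, L - 2)
        startpos = int(rng.integers(1, L - tract_len))  # internal only
        tract = list(range(startpos, startpos + tract_len))
        for j in tract:
            transmitted[j] = haps[1 - source[j]][j]
        events.append({"type": "conversion", "loci": [names[j] for j in tract]})

    for j in range(L):
        if rng.random() < indel_prob:
            unit = panel[j].repeat_unit
            sign = 1 if rng.random() < 0.5 else -1
            old = transmitted[j]
            transmitted[j] = old + sign * unit
            events.append(
                {"type": "insertion" if sign > 0 else "deletion",
                 "locus": names[j], "from": old, "to": transmitted[j]}
            )
    return tuple(transmitted), events, start


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig) -> tuple[PopulationDataset, TruthLog]:
    """Founders plus trio offspring; dam and sire each contribute one meiosis.

    Mating is deterministic round-robin (offspring i of a population takes
    dam i mod n_dams and sire i mod n_sires), mirroring a stud design where
    mares mostly have one offspring per season and stallions serve several.
    """
    founders, pools, phases = sample_founders(config)
    names = config.panel.names
    individuals = list(founders)
    meioses: list[TruthMeiosis] = []

    for p_idx, pc in enumerate(config.populations):
        dams = [f"{pc.name}_D{i + 1:03d}" for i in range(pc.n_founder_dams)]
        sires = [f"{pc.name}_S{i + 1:03d}" for i in range(pc.n_founder_sires)]
        for o in range(pc.n_offspring):
            oid = f"{pc.name}_O{o + 1:03d}"
            dam = dams[o % len(dams)]
            sire = sires[o % len(sires)]
            geno_parts = {}
            for side_idx, (sex, pid) in enumerate((("dam", dam), ("sire", sire))):
                rng = np.random.default_rng([config.seed, 0xA1, p_idx, o, side_idx])
                transmitted, events, start = simulate_meiosis(
                    phases[pid], config.panel,
                    config.crossover_prob, config.conversion_prob,
                    config.indel_prob, rng,
                )
                effectual = transmitted != phases[pid][0] and transmitted != phases[pid][1]
                meioses.append(
                    TruthMeiosis(
                        offspring_id=oid, parent_id=pid, parent_sex=sex,
                        start_haplotype=start, events=events,
                        transmitted=transmitted, effectual=effectual,
                    )
                )
                geno_parts[sex] = transmitted
            geno = {
                name: canonical_pair(geno_parts["dam"][j], geno_parts["sire"][j])
                for j, name in enumerate(names)
            }
            individuals.append(
                Individual(id=oid, population=pc.name, genotype=geno,
                           dam_id=dam, sire_id=sire)
            )
    dataset = PopulationDataset(panel=config.panel, individuals=individuals)
    truth = TruthLog(founders=phases, meioses=meioses, pools=pools)
    return dataset, truth


def replay_truth(truth: TruthLog, panel: LocusPanel) -> dict[str, dict[str, tuple]]:
    """Re-derive every offspring genotype from founder phases + logged events.

    Replays each meiosis from its start haplotype and event list (without
    touching the logged transmitted haplotype) and re-pairs the two gametes;
    used to verify the log is exhaustive and exact.
    """
    names = panel.names
    L = len(panel)
    per_offspring: dict[str, dict[str, tuple]] = {}
    for m in truth.meioses:
        haps = truth.founders[m.parent_id]
        source = [m.start_haplotype] * L
        cur = m.start_haplotype
        idx = {n: i for i, n in enumerate(names)}
        crossovers = [e for e in m.events if e["type"] == "crossover"]
        switch_after = {idx[e["interval"][0]] for e in crossovers}
        for i in range(1, L):
            if (i - 1) in switch_after:
                cur ^= 1
            source[i] = cur
        hap = [haps[source[i]][i] for i in range(L)]
        for e in m.events:
            if e["type"] == "conversion":
                for name in e["loci"]:
                    j = idx[name]
                    hap[j] = haps[1 - source[j]][j]
            elif e["type"] in ("insertion", "deletion"):
                hap[idx[e["locus"]]] = e["to"]
        per_offspring.setdefault(m.offspring_id, {})[m.parent_sex] = tuple(hap)
    return per_offspring


def write_dataset(dataset: PopulationDataset, truth: TruthLog, outdir) -> None:
    """Write genotypes.csv, pedigree.csv, truth.json and panel.json."""
    import os

    os.makedirs(outdir, exist_ok=True)
    dataset.to_dataframe().to_csv(os.path.join(outdir, "genotypes.csv"), index=False)
    ped = [
        {"id": ind.id, "sire": ind.sire_id or "", "dam": ind.dam_id or ""}
        for ind in dataset.individuals
    ]
    import pandas as pd

    pd.DataFrame(ped).to_csv(os.path.join(outdir, "pedigree.csv"), index=False)
    truth.to_json(os.path.join(outdir, "truth.json"))
    dataset.panel.to_json(os.path.join(outdir, "panel.json"))
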