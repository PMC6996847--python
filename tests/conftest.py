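import pytest

import equimhc as eq


@pytest.fixture(scope="session")
def panel():
    return eq.default_panel()


@pytest.fixture(scope="session")
def study_sim():
    """Study-sized three-population dataset (170 horses, 70 trios)."""
    cfg = eq.study_config(seed=7)
    return eq.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def big_sim():
    """Two populations, 1000 trios = 2000 meioses with planted events."""
    cfg = eq.SimConfig(
        panel=eq.default_panel(),
        populations=[
            eq.PopulationConfig("A", 125, 25, 500),
            eq.PopulationConfig("B", 125, 25, 500),
        ],
        founder_allele_counts=dict.fromkeys(eq.default_panel().names, 10),
        crossover_prob=0.0125,
        conversion_prob=0.02,
        indel_prob=0.0018,
        seed=11,
    )
    return eq.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def big_calls(big_sim):
    ds, truth = big_sim
    phased = eq.phase_population(ds)
    return ds, truth, phased, eq.call_events(ds, phased)


@pytest.fixture(scope="session")
def zero_rate_sim():
    """500 trios with all event rates zero (phasing ground truth)."""
    cfg = eq.SimConfig(
        panel=eq.default_panel(),
        populations=[eq.PopulationConfig("P", 250, 50, 500)],
        founder_allele_counts=dict.fromkeys(eq.default_panel().names, 10),
        crossover_prob=0.0,
        conversion_prob=0.0,
        indel_prob=0.0,
        seed=21,
    )
    return eq.simulate_dataset(cfg)


def write_genotype_csv(path, panel, rows):
    """rows: list of (id, population, {locus: (a, b) | None})."""
    cols = ["id", "population"]
    for name in panel.names:
        cols += [f"{name}.1", f"{name}.2"]
    lines = [",".join(cols)]
    for iid, pop, geno in rows:
        vals = [iid, pop]
        for name in panel.names:
            g = geno.get(name)
            vals += [str(g[0]), str(g[1])] if g else ["", ""]
        lines.append(",".join(vals))
    path.write_text("\n".join(lines) + "\n")
    return path


def write_pedigree_csv(path, rows):
    """rows: list of (id, sire, dam)."""
    lines = ["id,sire,dam"]
    for iid, sire, dam in rows:
        lines.append(f"{iid},{sire or ''},{dam or ''}")
    path.write_text("\n".join(lines) + "\n")
    return path
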