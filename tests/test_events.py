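"""Meiotic event classification and per-meiosis frequencies."""

import math

import pytest

import equimhc as eq
from equimhc import UndefinedStatisticError
from equimhc.events import explain_transmission


@pytest.fixture(scope="module")
def haps(panel):
    h1 = tuple(100 + 2 * i for i in range(len(panel)))
    h2 = tuple(200 + 2 * i for i in range(len(panel)))
    return h1, h2


class TestExplainTransmission:
    def test_exact_match_is_no_event(self, panel, haps):
        h1, h2 = haps
        assert explain_transmission((h1, h2), h1, panel).type == "none"
        assert explain_transmission((h1, h2), h2, panel).type == "none"

    def test_single_crossover_terminal_interval(self, panel, haps):
        h1, h2 = haps
        t = h1[:10] + h2[10:]
        e = explain_transmission((h1, h2), t, panel)
        assert e.type == "recombination"
        assert e.breakpoints == [("UM011", "COR114")]
        assert any("tie" in s for s in e.ties)

    def test_internal_single_locus_conversion(self, panel, haps):
        h1, h2 = haps
        t = list(h1)
        t[5] = h2[5]
        e = explain_transmission((h1, h2), tuple(t), panel)
        assert e.type == "conversion" and e.conversions == [["ABGe9030"]]
        assert e.breakpoints == []

    def test_two_locus_conversion_beats_double_crossover(self, panel, haps):
        h1, h2 = haps
        t = list(h1)
        t[4], t[5] = h2[4], h2[5]
        e = explain_transmission((h1, h2), tuple(t), panel)
        assert e.type == "conversion" and e.conversions == [["UMNe65", "ABGe9030"]]

    def test_wide_internal_segment_is_double_crossover(self, panel, haps):
        h1, h2 = haps
        t = list(h1)
        for j in (3, 4, 5, 6):
            t[j] = h2[j]
        e = explain_transmission((h1, h2), tuple(t), panel)
        assert e.type == "recombination" and len(e.breakpoints) == 2

    def test_repeat_unit_insertion_forced(self, panel, haps):
        h1, h2 = haps
        t = list(h1)
        t[4] = h1[4] + 2
        e = explain_transmission((h1, h2), tuple(t), panel)
        assert e.type == "insertion"
        assert e.indels == [("UMNe65", h1[4], h1[4] + 2)]

    def test_large_offset_unexplained(self, panel, haps):
        h1, h2 = haps
        t = list(h1)
        t[4] = h1[4] + 20  # ten repeat units away from h1, far from h2 too
        e = explain_transmission((h1, h2), tuple(t), panel)
        assert e.type == "unexplained"

    def test_duplication_pattern_calls_terminal_conversion(self, panel, haps):
        h1, h2 = haps
        t = h2[:1] + h1[1:]  # terminal single-locus switch at COR110
        off = [tuple(sorted((h1[i], h2[i]))) for i in range(len(panel))]
        off[0] = (h1[0], h2[0])  # offspring carries both of this parent's alleles
        other = [(900, 902)] * len(panel)  # other parent excluded everywhere
        e = explain_transmission(
            (h1, h2), t, panel, offspring_genotype=off, other_parent_genotype=other
        )
        assert e.type == "conversion"
        assert any("duplication" in s for s in e.ties)
        # without the duplication evidence the same mosaic is recombination
        e2 = explain_transmission((h1, h2), t, panel)
        assert e2.type == "recombination"

    def test_uninformative_loci_widen_breakpoint_interval(self, panel, haps):
        h1, h2 = haps
        h2 = list(h2)
        h2[5] = h1[5]  # ABGe9030 uninformative
        t = list(h1[:5]) + [h1[5]] + list(h2[6:])
        e = explain_transmission((h1, tuple(h2)), tuple(t), panel)
        assert e.type == "recombination"
        assert e.breakpoints == [("UMNe65", "TKY3324")]

    def test_too_few_comparable_loci_unexplained(self, panel, haps):
        h1, h2 = haps
        t = (h1[0],) + (None,) * 10
        e = explain_transmission((h1, h2), t, panel)
        assert e.type == "unexplained"


class TestCallEvents:
    def test_zero_rates_no_events(self, zero_rate_sim):
        ds, _ = zero_rate_sim
        calls = eq.call_events(ds, eq.phase_population(ds))
        cov = calls.coverage()
        assert cov["events"] == 0 and cov["unexplained"] == 0
        assert all(not r.is_new_haplotype for r in calls.records)

    def test_single_planted_crossover_recovered(self, panel):
        # dam with three offspring: two pure transmissions establish phase,
        # the third carries one crossover
        h1 = tuple(100 + 2 * i for i in range(11))
        h2 = tuple(200 + 2 * i for i in range(11))
        sire_hap = tuple(300 + 2 * i for i in range(11))
        recomb = h1[:6] + h2[6:]
        inds = [
            eq.Individual("dam", "P", {n: tuple(sorted((h1[i], h2[i])))
                                       for i, n in enumerate(panel.names)}),
            eq.Individual("sire", "P", {n: (sire_hap[i], sire_hap[i])
                                        for i, n in enumerate(panel.names)}),
        ]
        for k, hap in enumerate((h1, h2, recomb)):
            inds.append(
                eq.Individual(
                    f"o{k}", "P",
                    {n: tuple(sorted((hap[i], sire_hap[i])))
                     for i, n in enumerate(panel.names)},
                    dam_id="dam", sire_id="sire",
                )
            )
        ds = eq.PopulationDataset(panel=panel, individuals=inds)
        calls = eq.call_events(ds, eq.phase_population(ds))
        recomb_events = [e for e in calls.events if e.type == "recombination"]
        assert len(recomb_events) == 1
        (event,) = recomb_events
        assert event.offspring_id == "o2" and event.parent_sex == "dam"
        assert event.breakpoints == [(panel.names[5], panel.names[6])]
        assert event.is_new_haplotype

    def test_conservation_of_transmissions(self, big_calls):
        ds, _, _, calls = big_calls
        cov = calls.coverage()
        n_links = sum(
            (i.dam_id is not None) + (i.sire_id is not None)
            for i in ds.individuals if i.is_offspring
        )
        assert sum(cov.values()) == n_links == len(calls.records)

    def test_indel_offsets_are_repeat_unit_multiples(self, big_calls):
        ds, _, _, calls = big_calls
        units = {l.name: l.repeat_unit for l in ds.panel}
        indels = [e for e in calls.events if e.type in ("insertion", "deletion")]
        assert indels
        for e in indels:
            frm, to = e.allele_change
            assert (to - frm) % units[e.loci[0]] == 0 and to != frm

    def test_events_with_complete_haplotypes_are_new(self, big_calls):
        # every conversion produced a haplotype absent from the parental pool
        ds, _, _, calls = big_calls
        for r in calls.records:
            if r.status == "events" and all(a is not None for a in r.resulting_haplotype):
                if any(e.type == "conversion" for e in r.events):
                    assert r.is_new_haplotype

    def test_paternal_and_maternal_sides_both_observed(self, big_calls):
        _, _, _, calls = big_calls
        sexes = {e.parent_sex for e in calls.events}
        assert sexes == {"dam", "sire"}


class TestFrequencies:
    def test_per_meiosis_percent_requires_meioses(self):
        with pytest.raises(UndefinedStatisticError):
            eq.per_meiosis_percent(1, 0)

    def test_zero_events_zero_percent(self, zero_rate_sim):
        ds, _ = zero_rate_sim
        calls = eq.call_events(ds, eq.phase_population(ds))
        s = eq.event_frequencies(calls, ds, "P")
        assert s.recombination_frequency == 0.0
        assert s.new_haplotype_ratio == 0.0
        assert s.n_meioses == 2 * s.n_offspring  # all offspring are full trios

    def test_summary_counts_transmission_level(self, big_calls):
        ds, _, _, calls = big_calls
        for pop in ds.populations:
            s = eq.event_frequencies(calls, ds, pop)
            assert s.n_meioses == 1000
            for t, c in s.counts.items():
                assert 0 <= c <= s.n_meioses
            assert 0 <= s.recombination_frequency <= 100
            assert s.new_haplotype_ratio >= 0

    def test_new_haplotype_ratio_matches_pool_definition(self, big_calls):
        ds, _, phased, calls = big_calls
        inv = eq.haplotype_inventory(phased, ds)
        for pop in ds.populations:
            ratio = eq.new_haplotype_ratio(calls, inv, ds, pop)
            assert 0 <= ratio <= 100
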