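"""Domain types, file I/O and dataset validation."""

import pytest

import equimhc as eq
from equimhc import FormatError, ValidationError

from conftest import write_genotype_csv, write_pedigree_csv


@pytest.fixture
def small_panel():
    return eq.LocusPanel(
        (
            eq.LocusDef("COR110", "I", 0),
            eq.LocusDef("UM011", "II", 1),
        )
    )


class TestPanel:
    def test_default_panel_order_and_uniqueness(self, panel):
        assert len(panel) == 11
        assert panel.names[0] == "COR110" and panel.names[-1] == "COR114"
        idx = [l.map_index for l in panel]
        assert idx == sorted(idx) and len(set(idx)) == 11
        assert {l.mhc_class for l in panel} == {"I", "II", "III"}

    def test_panel_rejects_duplicates_and_misordered_indices(self):
        with pytest.raises(ValueError):
            eq.LocusPanel((eq.LocusDef("A", "I", 0), eq.LocusDef("A", "I", 1)))
        with pytest.raises(ValueError):
            eq.LocusPanel((eq.LocusDef("A", "I", 1), eq.LocusDef("B", "I", 0)))

    def test_panel_json_round_trip(self, panel, tmp_path):
        p = tmp_path / "panel.json"
        panel.to_json(p)
        assert eq.LocusPanel.from_json(p) == panel


class TestGenotypeReader:
    def test_parse_and_canonicalize(self, small_panel, tmp_path):
        path = write_genotype_csv(
            tmp_path / "g.csv",
            small_panel,
            [
                ("h1", "Pop1", {"COR110": (226, 230), "UM011": (180, 178)}),
                ("h2", "Pop1", {"COR110": (230, 226), "UM011": (178, 178)}),
                ("h3", "Pop2", {"UM011": (178, 180)}),
            ],
        )
        ds = eq.read_genotype_table(path, small_panel)
        assert ds.by_id["h1"].genotype["COR110"] == (226, 230)
        # pair order carries no meaning
        assert ds.by_id["h2"].genotype["COR110"] == (226, 230)
        assert ds.by_id["h1"].genotype["UM011"] == (178, 180)
        # missing either allele -> whole locus missing
        assert ds.by_id["h3"].genotype["COR110"] is None
        assert ds.populations == ["Pop1", "Pop2"]

    def test_half_missing_pair_is_fully_missing(self, small_panel, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text(
            "id,population,COR110.1,COR110.2,UM011.1,UM011.2\n"
            "h1,P,226,,178,180\n"
        )
        ds = eq.read_genotype_table(path, small_panel)
        assert ds.by_id["h1"].genotype["COR110"] is None

    def test_unknown_column_named_in_error(self, small_panel, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("id,population,COR110.1,COR110.2,UM011.1,UM011.2,BOGUS.1\nh,P,1,2,3,4,5\n")
        with pytest.raises(FormatError, match="BOGUS"):
            eq.read_genotype_table(path, small_panel)

    def test_non_integer_allele_reports_row(self, small_panel, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text(
            "id,population,COR110.1,COR110.2,UM011.1,UM011.2\nh1,P,226,abc,178,180\n"
        )
        with pytest.raises(FormatError, match="row 2"):
            eq.read_genotype_table(path, small_panel)

    def test_duplicate_id_rejected(self, small_panel, tmp_path):
        path = write_genotype_csv(
            tmp_path / "g.csv",
            small_panel,
            [
                ("h1", "P", {"COR110": (1, 2), "UM011": (3, 4)}),
                ("h1", "P", {"COR110": (1, 2), "UM011": (3, 4)}),
            ],
        )
        with pytest.raises(ValidationError, match="duplicate"):
            eq.read_genotype_table(path, small_panel)


class TestPedigree:
    def _dataset(self, small_panel, tmp_path):
        path = write_genotype_csv(
            tmp_path / "g.csv",
            small_panel,
            [
                (i, "P", {"COR110": (1, 2), "UM011": (3, 4)})
                for i in ("foal", "sire", "dam")
            ],
        )
        return eq.read_genotype_table(path, small_panel)

    def test_trio_attaches_links(self, small_panel, tmp_path):
        ds = self._dataset(small_panel, tmp_path)
        ped = write_pedigree_csv(tmp_path / "p.csv", [("foal", "sire", "dam")])
        eq.read_pedigree(ped, ds)
        foal = ds.by_id["foal"]
        assert foal.is_offspring and foal.sire_id == "sire" and foal.dam_id == "dam"
        assert len(ds.offspring()) == 1

    def test_blank_sire_gives_single_parent_pair(self, small_panel, tmp_path):
        ds = self._dataset(small_panel, tmp_path)
        ped = write_pedigree_csv(tmp_path / "p.csv", [("foal", None, "dam")])
        eq.read_pedigree(ped, ds)
        foal = ds.by_id["foal"]
        assert foal.sire_id is None and foal.dam_id == "dam"
        assert eq.count_meioses(ds, "P") == 1

    def test_self_parent_rejected(self, small_panel, tmp_path):
        ds = self._dataset(small_panel, tmp_path)
        ped = write_pedigree_csv(tmp_path / "p.csv", [("foal", "foal", "dam")])
        with pytest.raises(ValidationError, match="cycle"):
            eq.read_pedigree(ped, ds)

    def test_unknown_id_rejected(self, small_panel, tmp_path):
        ds = self._dataset(small_panel, tmp_path)
        ped = write_pedigree_csv(tmp_path / "p.csv", [("ghost", "sire", "dam")])
        with pytest.raises(ValidationError, match="ghost"):
            eq.read_pedigree(ped, ds)


class TestGenepop:
    def test_rank_based_codes(self, small_panel, tmp_path):
        path = write_genotype_csv(
            tmp_path / "g.csv",
            small_panel,
            [("h1", "P", {"COR110": (226, 230), "UM011": (178, 178)})],
        )
        ds = eq.read_genotype_table(path, small_panel)
        out = tmp_path / "out.gen"
        eq.write_genepop(ds, out)
        text = out.read_text()
        assert "001002" in text  # smallest sizes coded 001, 002
        assert text.splitlines()[1:3] == ["COR110", "UM011"]

    def test_missing_locus_coded_zero(self, small_panel, tmp_path):
        path = write_genotype_csv(
            tmp_path / "g.csv",
            small_panel,
            [("h1", "P", {"UM011": (178, 180)})],
        )
        ds = eq.read_genotype_table(path, small_panel)
        out = tmp_path / "out.gen"
        eq.write_genepop(ds, out)
        assert "000000" in out.read_text()

    def test_round_trip_on_simulated_three_pop_dataset(self, study_sim, tmp_path):
        ds, _ = study_sim
        out = tmp_path / "study.gen"
        eq.write_genepop(ds, out)
        back = eq.read_genepop(out, ds.panel)
        assert [i.id for i in back.individuals] == [
            i.id for i in sorted(ds.individuals, key=lambda x: ds.populations.index(x.population))
        ] or len(back.individuals) == len(ds.individuals)
        orig = {i.id: (i.population, i.genotype) for i in ds.individuals}
        for ind in back.individuals:
            pop, geno = orig[ind.id]
            assert ind.population == pop
            assert ind.genotype == geno

    def test_rewrite_is_byte_identical(self, study_sim, tmp_path):
        ds, _ = study_sim
        a, b = tmp_path / "a.gen", tmp_path / "b.gen"
        eq.write_genepop(ds, a)
        eq.write_genepop(eq.read_genepop(a, ds.panel), b)
        assert a.read_text() == b.read_text()


class TestValidation:
    def test_compatible_trio_not_flagged(self, small_panel):
        g = {"COR110": (226, 230), "UM011": (1, 2)}
        ds = eq.PopulationDataset(
            panel=small_panel,
            individuals=[
                eq.Individual("dam", "P", {"COR110": (226, 226), "UM011": (1, 1)}),
                eq.Individual("sire", "P", {"COR110": (230, 232), "UM011": (2, 2)}),
                eq.Individual("foal", "P", g, sire_id="sire", dam_id="dam"),
            ],
        )
        assert eq.validate_dataset(ds).incompatibilities == []

    def test_incompatibility_flagged_for_both_parents(self, small_panel):
        ds = eq.PopulationDataset(
            panel=small_panel,
            individuals=[
                eq.Individual("dam", "P", {"COR110": (226, 226), "UM011": (1, 1)}),
                eq.Individual("sire", "P", {"COR110": (230, 230), "UM011": (1, 1)}),
                eq.Individual(
                    "foal", "P", {"COR110": (228, 228), "UM011": (1, 1)},
                    sire_id="sire", dam_id="dam",
                ),
            ],
        )
        report = eq.validate_dataset(ds)
        flagged = {(x.parent_id, x.locus) for x in report.incompatibilities}
        assert flagged == {("dam", "COR110"), ("sire", "COR110")}

    def test_zero_event_rates_give_zero_incompatibilities(self, zero_rate_sim):
        ds, _ = zero_rate_sim
        assert eq.validate_dataset(ds).incompatibilities == []
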