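"""Checklist I/O, rank inference, and name normalization."""

import pytest

from mycocheck import (SynonymTable, clean_name, collapse_to_species,
                       infer_rank, normalize_names, read_checklist,
                       simulate_checklist, SimulationConfig, inject_name_noise)
from mycocheck.checklist import Checklist
from mycocheck.errors import (ChecklistSchemaError, RankError,
                              SynonymResolutionError)
from tests.conftest import make_records


class TestReadChecklist:
    def test_parses_tsv_rows(self, tmp_path):
        p = tmp_path / "cl.tsv"
        p.write_text("scientificName\tcountry\tbibliographicCitation\tyear\n"
                     "Meliola clerodendricola\tBJ\tpub1\t2017\n"
                     "Puccinia graminis\tTG\tpub2\t\n"
                     "Russula cellulata\tGH\tpub2\t1990\n")
        cl = read_checklist(p, delimiter="\t")
        assert len(cl) == 3
        assert cl.records[0].year == 2017 and cl.records[1].year is None
        assert cl.validation.clean

    def test_unknown_country_is_flagged_not_dropped(self, tmp_path):
        p = tmp_path / "cl.csv"
        p.write_text("scientificName,country,bibliographicCitation\n"
                     "Meliola clerodendricola,Atlantis,pub1\n")
        cl = read_checklist(p)
        assert len(cl) == 1
        assert cl.validation.unknown_countries == [(0, "Atlantis")]

    def test_missing_mandatory_column_is_schema_error(self, tmp_path):
        p = tmp_path / "cl.csv"
        p.write_text("country,bibliographicCitation\nBJ,pub1\n")
        with pytest.raises(ChecklistSchemaError, match="scientificName"):
            read_checklist(p)


class TestNames:
    @pytest.mark.parametrize("raw,expected", [
        ("Meliola clerodendricola", "Meliola clerodendricola"),
        ("Puccinia graminis var. tritici", "Puccinia graminis"),
        ("Puccinia graminis subsp. graminicola x", "Puccinia graminis"),
        ("  puccinia   graminis f. avenae", "Puccinia graminis"),
    ])
    def test_collapse_to_species(self, raw, expected):
        assert collapse_to_species(raw) == expected

    @pytest.mark.parametrize("raw", ["Russula", "Russula sp.", "Boletus cf. edulis"])
    def test_non_species_names_raise_rank_error(self, raw):
        with pytest.raises(RankError):
            collapse_to_species(raw)

    @pytest.mark.parametrize("raw,rank", [
        ("Puccinia graminis", "species"),
        ("Puccinia graminis var. tritici", "infraspecific"),
        ("Russula", "supraspecific"),
        ("Hohenbuehelia aff. grisea", "supraspecific"),
    ])
    def test_rank_inference(self, raw, rank):
        assert infer_rank(raw) == rank

    def test_clean_name_normalizes_genus_case_and_whitespace(self):
        assert clean_name("  PUCCINIA  graminis ") == "Puccinia graminis"
        assert clean_name("x Puccinia graminis") == "Puccinia graminis"


class TestSynonymTable:
    def test_chain_resolves_to_accepted(self):
        syn = SynonymTable({
            "A aa": ("synonym", "B bb"),
            "B bb": ("synonym", "C cc"),
            "C cc": ("accepted", "C cc"),
        })
        assert syn.resolve("A aa") == ("synonym", "C cc")

    def test_cycle_raises(self):
        syn = SynonymTable({"A aa": ("synonym", "B bb"), "B bb": ("synonym", "A aa")})
        with pytest.raises(SynonymResolutionError, match="cyclic"):
            syn.resolve("A aa")

    def test_overdeep_chain_raises(self):
        entries = {f"S{i} sp": ("synonym", f"S{i+1} sp") for i in range(8)}
        entries["S8 sp"] = ("accepted", "S8 sp")
        syn = SynonymTable(entries, max_depth=3)
        with pytest.raises(SynonymResolutionError, match="deeper"):
            syn.resolve("S0 sp")

    def test_accepted_must_map_to_self(self):
        with pytest.raises(SynonymResolutionError):
            SynonymTable({"A aa": ("accepted", "B bb")})


class TestNormalizeNames:
    def test_synonym_substitution_is_logged(self, toy_synonyms):
        cl = Checklist(records=make_records([
            ("Cercosporina arachidicola", "BJ", "pub1")]))
        norm, log = normalize_names(cl, toy_synonyms)
        assert norm.records[0].species_name == "Cercospora arachidicola"
        assert log.substitutions == [("Cercosporina arachidicola",
                                      "Cercospora arachidicola")]

    def test_unknown_name_kept_verbatim_and_logged(self, toy_synonyms):
        cl = Checklist(records=make_records([("Aecidium flavidum", "BJ", "pub1")]))
        norm, log = normalize_names(cl, toy_synonyms)
        assert norm.records[0].species_name == "Aecidium flavidum"
        assert log.unknown == ["Aecidium flavidum"]

    def test_supraspecific_drop_count(self, toy_synonyms):
        cl = Checklist(records=make_records([
            ("Puccinia graminis", "BJ", "p1"), ("Russula", "BJ", "p1"),
            ("Aecidium flavidum", "TG", "p2"), ("Boletus", "TG", "p2"),
            ("Cercosporina arachidicola", "TG", "p3")]))
        norm, log = normalize_names(cl, toy_synonyms, drop_supraspecific=True)
        assert len(norm) == 3
        assert len(log.dropped_supraspecific) == 2
        assert len(norm) == len(cl) - len(log.dropped_supraspecific)

    def test_infraspecific_collapse(self, toy_synonyms):
        cl = Checklist(records=make_records([
            ("Puccinia graminis var. tritici", "BJ", "p1")]))
        norm, log = normalize_names(cl, toy_synonyms)
        assert norm.records[0].species_name == "Puccinia graminis"
        assert log.collapsed == [("Puccinia graminis var. tritici",
                                  "Puccinia graminis")]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_idempotent_on_noisy_simulated_checklists(self, seed):
        cl, gt = simulate_checklist(SimulationConfig(S_true=80, n_publications=25,
                                                     seed=seed))
        noisy, _ = inject_name_noise(cl, gt, 0.5, 0.0, seed=seed)
        once, _ = normalize_names(noisy, gt.synonym_table)
        twice, log2 = normalize_names(once, gt.synonym_table)
        assert [r.species_name for r in twice] == [r.species_name for r in once]
        assert log2.empty

    def test_species_count_contractive(self, sim_small):
        cl, gt = sim_small
        noisy, _ = inject_name_noise(cl, gt, 0.7, 0.0, seed=11)
        norm, _ = normalize_names(noisy, gt.synonym_table)
        assert len(norm.species_set()) <= len(noisy.species_set())
        assert len(norm) == len(noisy)
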