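"""Disease, HLA and drug lexicon tests."""

from __future__ import annotations

import pytest

from hlalit.fixtures import generate_lexicon_sources
from hlalit.lexicons import (
    build_disease_lexicon,
    build_drug_lexicon,
    build_hla_lexicon,
    collapse_two_digit,
    normalize_allele,
    normalize_disease,
    parse_allele_name,
    read_allele_history,
    read_allele_list,
    read_mesh_tree,
    read_mrconso,
    surface_variants,
)


@pytest.fixture(scope="module")
def sources(tmp_path_factory):
    return generate_lexicon_sources(str(tmp_path_factory.mktemp("lexsrc")))


@pytest.fixture(scope="module")
def disease_lexicon(sources):
    return build_disease_lexicon(
        read_mrconso(sources["mrconso"]), read_mesh_tree(sources["mesh_tree"])
    )


class TestDiseaseLexicon:
    def test_dev_rows_excluded(self, disease_lexicon):
        assert all(e.descriptor_type != "DEV" for e in disease_lexicon.entries)
        assert disease_lexicon.lookup("abdominal inj") is None

    def test_synonyms_share_mesh_id(self, disease_lexicon):
        ids = {normalize_disease(s, disease_lexicon)[0]
               for s in ("cancer", "malignancy", "neoplasm", "tumor")}
        assert ids == {"D009369"}

    def test_type1_diabetes_variants_share_id(self, disease_lexicon):
        a = normalize_disease("type 1 diabetes", disease_lexicon)[0]
        b = normalize_disease("diabetes mellitus", disease_lexicon)[0]
        assert a == b == "D003922"

    def test_plural_variant_generated(self, disease_lexicon):
        e = disease_lexicon.lookup("tumors")
        assert e is not None and e.mesh_id == "D009369"
        assert e.descriptor_type == "plural-variant"

    def test_level_one_ancestor(self, disease_lexicon):
        mesh_id, level_one = normalize_disease("multiple sclerosis", disease_lexicon)
        assert mesh_id == "D009103"
        # first tree number sorted is C10.114.375 -> level one = C10.114
        assert level_one == "Autoimmune Diseases of the Nervous System"

    def test_unknown_keyword_raises(self, disease_lexicon):
        with pytest.raises(LookupError):
            normalize_disease("made-up disease", disease_lexicon)

    def test_unknown_descriptor_type_skipped(self, disease_lexicon):
        rows = [("thing", "XX", "D000001"), ("fever", "MH", "D005334")]
        lex = build_disease_lexicon(rows, disease_lexicon.hierarchy)
        assert lex.lookup("thing") is None and lex.lookup("fever") is not None


@pytest.fixture(scope="module")
def allele_map(sources):
    import yaml

    groups = yaml.safe_load(open(sources["hla_groups"]))
    return build_hla_lexicon(
        [name for _, name in read_allele_list(sources["allele_list"])],
        read_allele_history(sources["allele_history"]),
        broad_antigens=groups["broad_antigens"],
        haplotypes=groups["haplotypes"],
        generic_keywords=groups["generic_keywords"],
    )


class TestHlaLexicon:
    def test_parse_allele_name(self):
        assert parse_allele_name("HLA-B*13:01") == ("B", ("13", "01"))
        assert parse_allele_name("DRB1*15:01") == ("DRB1", ("15", "01"))

    def test_printed_variant_set_generated(self):
        got = surface_variants("HLA-B*13:01")
        for s in ("hla-b*13:01", "hla-b*1301", "b*1301", "b(*)1301", "b1301"):
            assert s in got

    def test_all_printed_surfaces_normalize_to_one_canonical(self, allele_map):
        canons = {
            normalize_allele(s, allele_map).canonical
            for s in ("HLA-B*13:01", "HLA-B*1301", "B*1301", "B(*)1301", "B1301")
        }
        assert canons == {"HLA-B*13:01"}

    def test_normalization_idempotent_over_all_surfaces(self, allele_map):
        for surface in allele_map.surfaces:
            n1 = normalize_allele(surface, allele_map)
            n2 = normalize_allele(n1.canonical, allele_map)
            if not n1.ambiguous:
                assert n2.candidates == n1.candidates

    def test_every_generated_surface_roundtrips(self, allele_map):
        for name in (n for _, n in read_allele_list_rows()):
            gene, fields = parse_allele_name(name)
            canonical = f"HLA-{gene}*{':'.join(fields)}"
            for s in surface_variants(canonical):
                assert canonical in normalize_allele(s, allele_map).candidates

    def test_history_mapping(self, allele_map):
        n = normalize_allele("Cw*0602", allele_map)
        assert n.canonical == "HLA-C*06:02" and not n.ambiguous

    def test_retired_allele_excluded(self, allele_map):
        with pytest.raises(LookupError):
            normalize_allele("A*9901", allele_map)

    def test_broad_antigen_flagged_with_candidates(self, allele_map):
        n = normalize_allele("HLA-A9", allele_map)
        assert n.ambiguous and set(n.candidates) == {"HLA-A*23", "HLA-A*24"}
        assert n.canonical == "HLA-A9"

    def test_generic_keywords_present(self, allele_map):
        assert "hla class i" in allele_map
        assert normalize_allele("HLA class II", allele_map).canonical == "HLA class II"

    def test_unknown_surface_raises(self, allele_map):
        with pytest.raises(LookupError):
            normalize_allele("b9999", allele_map)


def read_allele_list_rows():
    from hlalit.fixtures import ALLELE_LIST_ROWS

    return ALLELE_LIST_ROWS


class TestCollapseTwoDigit:
    @pytest.mark.parametrize(
        "name,collapsed",
        [
            ("HLA-B*13:01", "HLA-B*13"),
            ("HLA-DRB1*15", "HLA-DRB1*15"),
            ("HLA-B*38:02:01", "HLA-B*38"),
        ],
    )
    def test_examples(self, name, collapsed):
        assert collapse_two_digit(name) == collapsed

    def test_idempotent(self):
        for name in ("HLA-B*13:01", "HLA-A*31:01:02", "HLA-DQB1*06:02"):
            once = collapse_two_digit(name)
            assert collapse_two_digit(once) == once

    def test_generic_not_collapsible(self):
        with pytest.raises(ValueError):
            collapse_two_digit("HLA class I")


class TestDrugLexicon:
    def test_union_with_overlap(self):
        lex = build_drug_lexicon(
            ["a", "b", "c", "d", "e"],
            {"AFND": ["f", "g"], "PharmGKB": ["h", "a"]},
        )
        assert len(lex) == 8
        a = next(d for d in lex if d.name == "a")
        assert set(a.sources) == {"SIDER", "PharmGKB"}

    def test_case_folded_dedupe(self):
        lex = build_drug_lexicon(["Carbamazepine"], {"PharmGKB": ["carbamazepine"]})
        assert len(lex) == 1

    def test_empty_input_warns(self, caplog):
        with caplog.at_level("WARNING"):
            assert build_drug_lexicon([]) == []
        assert any("empty" in r.message for r in caplog.records)
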