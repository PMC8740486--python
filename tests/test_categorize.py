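"""Category rules, biomarker query and export round-trip tests."""

from __future__ import annotations

import filecmp
import os

import pytest

from hlalit.categorize import (
    biomarker_query,
    categorize_abstract,
    export_tables,
    import_tables,
)
from hlalit.types import MentionKind, StudyCategory


def _annotate(pipeline, text, pmid="1"):
    from hlalit.types import AbstractRecord

    rec = AbstractRecord(pmid=pmid, title="t", abstract_text=text,
                         pub_date="2000", journal="J",
                         article_types=["Journal Article"])
    return pipeline.annotate_record(rec)


class TestCategorizeAbstract:
    def test_e04_keyword_is_transplantation(self, pipeline, resources):
        anns = _annotate(pipeline, "HLA-B27 was strongly associated with kidney transplantation.")
        cats = categorize_abstract(anns, resources.disease_lexicon)
        assert cats == {StudyCategory.TRANSPLANTATION}

    def test_gvhd_subtree_is_transplantation(self, pipeline, resources):
        anns = _annotate(pipeline, "HLA-DRB1*15 was strongly associated with graft-versus-host disease.")
        cats = categorize_abstract(anns, resources.disease_lexicon)
        assert cats == {StudyCategory.TRANSPLANTATION}

    def test_c23_subtree_is_signs_symptoms(self, pipeline, resources):
        anns = _annotate(pipeline, "HLA-B27 was significantly associated with fever.")
        cats = categorize_abstract(anns, resources.disease_lexicon)
        assert cats == {StudyCategory.SIGNS_SYMPTOMS}

    def test_induced_token_with_triple_comention_is_adr(self, pipeline, resources):
        anns = _annotate(
            pipeline,
            "Carbamazepine-induced Stevens-Johnson syndrome was significantly "
            "associated with HLA-B*15:02 in Han patients.",
        )
        cats = categorize_abstract(anns, resources.disease_lexicon)
        assert StudyCategory.THERAPEUTICS_ADR in cats

    def test_induced_disease_keyword_is_adr(self, pipeline, resources):
        anns = _annotate(
            pipeline,
            "Drug-induced liver injury was significantly associated with "
            "HLA-B*57:01 in patients receiving allopurinol.",
        )
        cats = categorize_abstract(anns, resources.disease_lexicon)
        assert StudyCategory.THERAPEUTICS_ADR in cats

    def test_adr_requires_drug_comention(self, pipeline, resources):
        # same disease but no drug in the sentence: not ADR
        anns = _annotate(pipeline, "HLA-B*15:02 was significantly associated "
                                   "with Stevens-Johnson syndrome.")
        cats = categorize_abstract(anns, resources.disease_lexicon)
        assert StudyCategory.THERAPEUTICS_ADR not in cats
        assert StudyCategory.DISEASES in cats

    def test_adr_implies_triple_comention(self, pipeline, resources, corpus, parsed_records):
        for rec in parsed_records:
            anns = pipeline.annotate_record(rec)
            cats = categorize_abstract(anns, resources.disease_lexicon)
            if StudyCategory.THERAPEUTICS_ADR in cats:
                assert any(
                    a.mentions_of(MentionKind.DRUG)
                    and a.mentions_of(MentionKind.ALLELE)
                    and a.mentions_of(MentionKind.DISEASE)
                    for a in anns
                )

    def test_exclusive_mode_single_category(self, pipeline, resources):
        anns = _annotate(
            pipeline,
            "Carbamazepine-induced Stevens-Johnson syndrome was significantly "
            "associated with HLA-B*15:02 in Han patients.",
        )
        cats = categorize_abstract(anns, resources.disease_lexicon, exclusive=True)
        assert cats == {StudyCategory.THERAPEUTICS_ADR}


class TestBiomarkerQuery:
    def test_ranking_by_frequency(self):
        sentences = (
            ["HLA-B27 is a genetic marker of risk."] * 3
            + ["It is a risk marker in cohorts."]
        )
        got = biomarker_query(sentences)
        assert got[0] == ("genetic marker", 3)
        assert ("risk marker", 1) in got

    def test_anchor_absent(self):
        assert biomarker_query(["No anchors here."]) == []

    def test_predictive_marker_contributes(self):
        got = biomarker_query(
            ["HLA-B*57:01 is a predictive marker for abacavir hypersensitivity."]
        )
        assert ("predictive marker", 1) in got


class TestExportRoundTrip:
    @pytest.fixture(scope="class")
    def bundle(self, pipeline, parsed_records):
        return pipeline.run(parsed_records).export_bundle()

    def test_roundtrip_lossless(self, bundle, tmp_path):
        export_tables(bundle, str(tmp_path / "out"))
        back = import_tables(str(tmp_path / "out"))
        for name in ("abstracts", "mentions", "sentence_labels", "categories",
                     "populations", "snps"):
            a, b = getattr(bundle, name), getattr(back, name)
            assert a.astype(str).equals(b.astype(str)), name
        assert back.summary == bundle.summary

    def test_empty_run_writes_headers(self, tmp_path):
        from hlalit.categorize import build_export_bundle

        empty = build_export_bundle([], {}, {}, {})
        export_tables(empty, str(tmp_path / "empty"))
        header = open(tmp_path / "empty" / "mentions.tsv").readline()
        assert header.startswith("pmid\tsentence_index\tkind")

    def test_same_run_twice_is_byte_identical(self, bundle, pipeline,
                                              parsed_records, tmp_path):
        export_tables(bundle, str(tmp_path / "a"))
        bundle2 = pipeline.run(parsed_records).export_bundle()
        export_tables(bundle2, str(tmp_path / "b"))
        for fname in os.listdir(tmp_path / "a"):
            assert filecmp.cmp(tmp_path / "a" / fname, tmp_path / "b" / fname,
                               shallow=False), fname
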