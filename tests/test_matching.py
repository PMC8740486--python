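"""Dictionary NER tests: boundary semantics, longest-match, screening and
brute-force oracle equivalence."""

from __future__ import annotations

import random

import pytest

from hlalit.matching import (
    ALLELE_WORD_CHARS,
    PLAIN_WORD_CHARS,
    DictionaryMatcher,
    filter_cooccurrence_sentences,
    match_alleles,
    match_diseases,
    screen_abstract,
)
from hlalit.text import preprocess_variants
from hlalit.types import AbstractRecord, SentenceAnnotation

from tests.conftest import make_sentence
from tests.oracles import brute_force_keyword_spans


class TestMatchDiseases:
    def test_special_character_variant_matches(self, resources):
        s = make_sentence("Cases of Stevens Johnson syndrome were reviewed.")
        got = match_diseases(s, resources.disease_lexicon)
        assert [m.surface for m in got] == ["Stevens Johnson syndrome"]
        assert got[0].canonical == "D013262"

    def test_no_lexicon_word(self, resources):
        assert match_diseases(make_sentence("Nothing relevant here."),
                              resources.disease_lexicon) == []

    def test_longest_match_wins(self, resources):
        s = make_sentence("Patients with insulin dependent diabetes mellitus enrolled.")
        got = match_diseases(s, resources.disease_lexicon)
        assert [m.surface for m in got] == ["insulin dependent diabetes mellitus"]

    def test_offsets_slice_sentence(self, resources):
        s = make_sentence("Graves' disease and cancer were studied.")
        for m in match_diseases(s, resources.disease_lexicon):
            assert s.text[m.char_start:m.char_end] == m.surface


class TestMatchAlleles:
    def test_bare_variant_normalized(self, resources):
        s = make_sentence("Carriers of B*1301 were enrolled.")
        got = match_alleles(s, resources.allele_map)
        assert [(m.surface, m.canonical) for m in got] == [("B*1301", "HLA-B*13:01")]

    def test_embedded_token_not_matched(self, resources):
        s = make_sentence("We used the probe 4B1301X for typing.")
        assert match_alleles(s, resources.allele_map) == []

    def test_star_boundary_handled(self, resources):
        s = make_sentence("HLA-B*15:02 carriage was typed.")
        got = match_alleles(s, resources.allele_map)
        assert [m.canonical for m in got] == ["HLA-B*15:02"]


class TestScreenAbstract:
    @pytest.fixture(scope="class")
    def matchers(self, resources):
        return (
            DictionaryMatcher(resources.allele_map.surfaces, ALLELE_WORD_CHARS),
            DictionaryMatcher(resources.disease_lexicon.surface_index, PLAIN_WORD_CHARS),
        )

    def rec(self, title, text):
        return AbstractRecord(pmid="1", title=title, abstract_text=text,
                              pub_date="2000", journal="J",
                              article_types=["Journal Article"])

    def test_title_allele_text_disease_kept(self, matchers):
        r = self.rec("HLA-B27 in a cohort", "We studied ankylosing spondylitis.")
        assert screen_abstract(r, *matchers)

    def test_neither_entity_dropped(self, matchers):
        assert not screen_abstract(self.rec("A title", "Plain text only."), *matchers)

    def test_allele_only_dropped(self, matchers):
        assert not screen_abstract(self.rec("HLA-B27 typing", "Methods text."), *matchers)


class TestCooccurrenceFilter:
    def test_exactly_comention_sentences_retained(self, resources):
        texts = [
            "HLA-DRB1*15 was protective for pulmonary tuberculosis.",   # both
            "The cohort comprised 200 patients.",                       # neither
            "HLA-B27 was typed by PCR.",                                # allele only
            "Cancer incidence rose.",                                   # disease only
            "B*1502 carriers developed Stevens-Johnson syndrome.",      # both
            "No further findings.",                                     # neither
        ]
        anns = []
        for i, t in enumerate(texts):
            s = make_sentence(t, index=i)
            anns.append(SentenceAnnotation(
                sentence=s,
                mentions=match_alleles(s, resources.allele_map)
                + match_diseases(s, resources.disease_lexicon),
            ))
        kept = filter_cooccurrence_sentences(anns)
        assert [a.sentence.index for a in kept] == [0, 4]


def _random_sentences(rng, n):
    from hlalit.fixtures import ALLELES, GEN_DISEASES, ADR_DISEASES

    alleles = [s for forms in ALLELES.values() for s in forms]
    diseases = [d for d, _ in GEN_DISEASES + ADR_DISEASES]
    noise = ("patients", "cohort", "4B1301X", "screening", "the", "B*9999",
             "probe", "rs123", "control", "typing", "HLA", "antigen2")
    out = []
    for _ in range(n):
        words = []
        for _ in range(rng.randint(3, 12)):
            r = rng.random()
            if r < 0.25:
                words.append(rng.choice(alleles))
            elif r < 0.45:
                words.append(rng.choice(diseases))
            else:
                words.append(rng.choice(noise))
        out.append(" ".join(words) + ".")
    return out


class TestOracleEquivalence:
    """The compiled matchers must agree with the exhaustive brute-force
    scanner on randomized sentences (spans only; canonicalization is
    downstream of span finding)."""

    def test_alleles_agree_with_brute_force(self, resources):
        rng = random.Random(5)
        matcher = DictionaryMatcher(resources.allele_map.surfaces, ALLELE_WORD_CHARS)
        for text in _random_sentences(rng, 50):
            s = make_sentence(text)
            got = [(m.char_start, m.char_end) for m in
                   match_alleles(s, resources.allele_map, matcher)]
            want = brute_force_keyword_spans(
                text, resources.allele_map.surfaces, "*:")
            assert got == want, text

    def test_diseases_agree_with_brute_force(self, resources):
        rng = random.Random(6)
        matcher = DictionaryMatcher(resources.disease_lexicon.surface_index,
                                    PLAIN_WORD_CHARS)
        for text in _random_sentences(rng, 50):
            s = make_sentence(text)
            got = [(m.char_start, m.char_end) for m in
                   match_diseases(s, resources.disease_lexicon, matcher)]
            want = brute_force_keyword_spans(
                text, resources.disease_lexicon.surface_index)
            assert got == want, text


class TestScreenFilterConsistency:
    def test_unscreened_record_yields_no_retained_sentences(self, resources, pipeline):
        """screen_abstract(record) == False implies the co-occurrence filter
        retains nothing from that record."""
        from hlalit.matching import screen_abstract

        rec = AbstractRecord(
            pmid="9", title="A methods note.",
            abstract_text="HLA-B27 was typed. Controls were recruited.",
            pub_date="2000", journal="J", article_types=["Journal Article"],
        )
        assert not screen_abstract(rec, pipeline.allele_matcher,
                                   pipeline.disease_matcher)
        assert pipeline.annotate_record(rec) == []


class TestMonotonicity:
    def test_adding_keyword_never_loses_sentences(self, resources):
        """Growing the disease lexicon cannot shrink the retained set."""
        texts = _random_sentences(random.Random(7), 30)
        sentences = [make_sentence(t, index=i) for i, t in enumerate(texts)]

        def retained(surfaces):
            matcher = DictionaryMatcher(surfaces, PLAIN_WORD_CHARS)
            kept = set()
            for s in sentences:
                if match_alleles(s, resources.allele_map) and matcher.scan(
                    preprocess_variants(s.text)
                ):
                    kept.add(s.index)
            return kept

        base_surfaces = [e.surface for e in resources.disease_lexicon.entries][:5]
        grown = base_surfaces + ["cancer", "fever", "multiple sclerosis"]
        assert retained(base_surfaces) <= retained(grown)
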