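"""Semantic labeling tests: coding vectors, guard, masking, root verb,
decision tables and n-gram harvesting."""

from __future__ import annotations

import itertools

import pytest

from hlalit.matching import match_alleles, match_diseases
from hlalit.semantics import (
    STAGE1_TABLE,
    HeuristicRootFinder,
    LabelLexicon,
    NgramConfig,
    VerbPolarity,
    annotate_sentence,
    build_ngram_candidates,
    code_to_stage1_label,
    detect_labels,
    mask_entities,
    root_verb,
)
from hlalit.text import PosTagger, tokenize
from hlalit.types import CodingVector, SentenceLabel, Stage1Label, VerbClass

from tests.conftest import make_sentence


@pytest.fixture(scope="module")
def lex():
    return LabelLexicon.load_default()


@pytest.fixture(scope="module")
def verbs():
    return VerbPolarity.load_default()


def _mentions(resources, sentence):
    return match_alleles(sentence, resources.allele_map) + match_diseases(
        sentence, resources.disease_lexicon
    )


class TestDetectLabels:
    def test_positive_cue_sets_positive_bit(self, resources, lex):
        s = make_sentence("HLA-B27 was significantly associated with ankylosing spondylitis.")
        v = detect_labels(s, _mentions(resources, s), lex)
        assert v.as_tuple() == (1, 0, 0)

    def test_carrier_status_negative_is_guarded(self, resources, lex):
        s = make_sentence("HLA-B27 negative patients were reviewed for cancer.")
        v = detect_labels(s, _mentions(resources, s), lex)
        assert v.as_tuple() == (0, 0, 0)

    def test_negative_beyond_guard_window_counts(self, lex):
        # no allele mention at all: "negative association" is a real cue
        s = make_sentence("A negative association with the syndrome was seen.")
        v = detect_labels(s, [], lex)
        assert v.has_neg

    def test_negation_word(self, resources, lex):
        s = make_sentence("HLA-B27 was not significantly associated with cancer.")
        v = detect_labels(s, _mentions(resources, s), lex)
        assert v.as_tuple() == (1, 0, 1)

    def test_no_cues(self, lex):
        s = make_sentence("The cohort comprised several individuals.")
        assert detect_labels(s, [], lex).as_tuple() == (0, 0, 0)


class TestStage1Table:
    def test_total_over_all_eight_vectors(self):
        for bits in itertools.product((0, 1), repeat=3):
            v = CodingVector(*map(bool, bits))
            assert code_to_stage1_label(v) in Stage1Label

    @pytest.mark.parametrize(
        "bits,label",
        [
            ((1, 0, 0), Stage1Label.POSITIVE),
            ((0, 1, 0), Stage1Label.NEGATIVE),
            ((1, 1, 0), Stage1Label.COMPLEX),
            ((1, 1, 1), Stage1Label.COMPLEX),
            ((1, 0, 1), Stage1Label.AMBIGUOUS),
            ((0, 1, 1), Stage1Label.AMBIGUOUS),
            ((0, 0, 1), Stage1Label.NEGATION),
            ((0, 0, 0), Stage1Label.OTHERS),
        ],
    )
    def test_mapping(self, bits, label):
        assert code_to_stage1_label(CodingVector(*map(bool, bits))) is label

    def test_table_covers_exactly_eight(self):
        assert len(STAGE1_TABLE) == 8


class TestMaskEntities:
    def test_multiword_disease_masked(self, resources):
        s = make_sentence("Multiple sclerosis is linked to HLA-DRB1*15.")
        masked = mask_entities(s, _mentions(resources, s))
        assert masked == "@DISEASE is linked to @GENE."

    def test_no_mentions_unchanged(self, resources):
        s = make_sentence("Nothing to mask here.")
        assert mask_entities(s, []) == s.text

    def test_two_alleles_one_disease(self, resources):
        s = make_sentence("B*1301 and HLA-B*15:02 were typed in cancer patients.")
        masked = mask_entities(s, _mentions(resources, s))
        assert masked.count("@GENE") == 2 and masked.count("@DISEASE") == 1

    def test_non_entity_tokens_preserved(self, resources):
        s = make_sentence("Multiple sclerosis is linked to HLA-DRB1*15.")
        mentions = _mentions(resources, s)
        masked = mask_entities(s, mentions)
        kept = [t.lower for t in tokenize(masked) if not t.text.startswith("@")]
        original = [t.lower for t in tokenize(s.text)]
        for surf in (m.surface for m in mentions):
            for tok in tokenize(surf):
                original.remove(tok.lower)
        assert sorted(kept) == sorted(original)

    def test_overlapping_mentions_raise(self, resources):
        from hlalit.types import Mention, MentionKind

        s = make_sentence("overlapping here")
        a = Mention(MentionKind.ALLELE, "overl", "x", 0, 5)
        b = Mention(MentionKind.DISEASE, "verla", "y", 1, 6)
        with pytest.raises(ValueError):
            mask_entities(s, [a, b])


class TestRootVerb:
    def test_purpose_clause_investigatory(self, verbs):
        lemma, klass = root_verb(
            "To investigate the association of @GENE with @DISEASE, we "
            "genotyped the cohort.", verbs,
        )
        assert (lemma, klass) == ("investigate", VerbClass.INVESTIGATORY)

    def test_copular_passive_roots_at_participle(self, verbs):
        lemma, klass = root_verb("@GENE is associated with @DISEASE.", verbs)
        assert (lemma, klass) == ("associate", VerbClass.POSITIVE)

    def test_empty_string(self, verbs):
        assert root_verb("", verbs) == ("", VerbClass.UNKNOWN)

    def test_unknown_verb(self, verbs):
        lemma, klass = root_verb("@GENE was genotyped in @DISEASE patients.", verbs)
        assert klass is VerbClass.UNKNOWN

    def test_custom_parser_interface(self, verbs):
        class FixedParser:
            def root_verb(self, text):
                return "protect"

        lemma, klass = root_verb("whatever", verbs, FixedParser())
        assert (lemma, klass) == ("protect", VerbClass.NEGATIVE)


class TestFinalDecisionTable:
    def test_total_over_grid(self):
        for s1, vc in itertools.product(Stage1Label, VerbClass):
            assert annotate_sentence(s1, vc) in SentenceLabel

    @pytest.mark.parametrize(
        "s1,vc,final",
        [
            (Stage1Label.POSITIVE, VerbClass.POSITIVE, SentenceLabel.POSITIVE),
            (Stage1Label.NEGATIVE, VerbClass.NEGATIVE, SentenceLabel.NEGATIVE),
            (Stage1Label.COMPLEX, VerbClass.POSITIVE, SentenceLabel.COMPLEX),
            (Stage1Label.AMBIGUOUS, VerbClass.POSITIVE, SentenceLabel.AMBIGUOUS),
            (Stage1Label.NEGATION, VerbClass.INVESTIGATORY, SentenceLabel.AMBIGUOUS),
            (Stage1Label.OTHERS, VerbClass.INVESTIGATORY, SentenceLabel.INVESTIGATORY),
            (Stage1Label.POSITIVE, VerbClass.INVESTIGATORY, SentenceLabel.INVESTIGATORY),
            (Stage1Label.POSITIVE, VerbClass.NEGATIVE, SentenceLabel.OTHERS),
            (Stage1Label.OTHERS, VerbClass.UNKNOWN, SentenceLabel.OTHERS),
        ],
    )
    def test_decision_rows(self, s1, vc, final):
        assert annotate_sentence(s1, vc) is final


class TestLabelLexicon:
    def test_polarity_sets_disjoint_and_nonempty(self, lex):
        assert lex.positive and lex.negative
        assert not lex.positive & lex.negative

    def test_default_negation_words(self, lex):
        assert lex.negation == {"not", "none", "no"}

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            LabelLexicon(frozenset({"x"}), frozenset({"x"}))


class TestNgramCandidates:
    @pytest.fixture(scope="class")
    def tagger(self, verbs):
        return PosTagger(set(verbs.classes) | {"associate"})

    def test_frequency_cutoff_and_count(self, tagger):
        corpus = ["The allele associated strongly."] * 12 + ["It linked."] * 3
        cfg = NgramConfig(n_values=frozenset({1}), freq_cutoff=5)
        got = build_ngram_candidates(corpus, cfg, tagger)
        assert ("associate", 12) in got
        assert all(c >= 5 for _, c in got)

    def test_adverb_verb_bigram_emitted(self, tagger):
        corpus = ["Alleles were strongly associated with outcomes."] * 4
        cfg = NgramConfig(n_values=frozenset({2}), freq_cutoff=2)
        got = build_ngram_candidates(corpus, cfg, tagger)
        assert ("strongly associate", 4) in got

    def test_cutoff_one_keeps_all_eligible(self, tagger):
        cfg = NgramConfig(n_values=frozenset({1}), freq_cutoff=1)
        got = build_ngram_candidates(["They strongly associated."], cfg, tagger)
        assert set(got) == {("strongly", 1), ("associate", 1)}

    def test_empty_corpus(self, tagger):
        cfg = NgramConfig(freq_cutoff=1)
        assert build_ngram_candidates([], cfg, tagger) == []

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NgramConfig(n_values=frozenset())
        with pytest.raises(ValueError):
            NgramConfig(freq_cutoff=0)
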