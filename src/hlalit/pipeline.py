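"""End-to-end orchestration: screen -> match -> tag -> label -> categorize.

The pipeline is deterministic given its inputs; no stage draws randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from hlalit.categorize import (
    ExportBundle,
    build_export_bundle,
    categorize_abstract,
)
from hlalit.config import ResourceBundle
from hlalit.matching import (
    ALLELE_WORD_CHARS,
    PLAIN_WORD_CHARS,
    DictionaryMatcher,
    filter_cooccurrence_sentences,
    match_alleles,
    match_diseases,
    screen_abstract,
)
from hlalit.medline import sentence_split
from hlalit.semantics import (
    HeuristicRootFinder,
    annotate_sentence,
    code_to_stage1_label,
    detect_labels,
    mask_entities,
    root_verb,
)
from hlalit.taggers import GazetteerNerBackend, NerBackend, tag_drugs, tag_snps
from hlalit.text import Lemmatizer
from hlalit.types import (
    AbstractRecord,
    Mention,
    MentionKind,
    PopulationTag,
    SentenceAnnotation,
    StudyCategory,
)


@dataclass
class PipelineResult:
    records: list[AbstractRecord]
    screened_pmids: list[str]
    annotations: dict[str, list[SentenceAnnotation]]  # retained sentences only
    categories: dict[str, set[StudyCategory]]
    populations: dict[str, list[PopulationTag]]

    def export_bundle(self) -> ExportBundle:
        screened = [r for r in self.records if r.pmid in set(self.screened_pmids)]
        return build_export_bundle(
            screened, self.annotations, self.categories, self.populations
        )


@dataclass
class Pipeline:
    """Reusable pipeline over compiled resources.

    Matchers are compiled once; the population NER backend defaults to the
    gazetteer over the curated tables and may be swapped for a model-based
    backend implementing :class:`~hlalit.taggers.NerBackend`.
    """

    resources: ResourceBundle
    guard_k: int = 2
    title_sentences: bool = False
    exclusive_categories: bool = False
    adr_tree_prefixes: Sequence[str] = ("C25.723",)
    ner_backend: NerBackend | None = None
    allele_matcher: DictionaryMatcher = field(init=False)
    disease_matcher: DictionaryMatcher = field(init=False)
    drug_matcher: DictionaryMatcher = field(init=False)

    def __post_init__(self) -> None:
        res = self.resources
        self.allele_matcher = DictionaryMatcher(res.allele_map.surfaces, ALLELE_WORD_CHARS)
        self.disease_matcher = DictionaryMatcher(res.disease_lexicon.surface_index, PLAIN_WORD_CHARS)
        self.drug_matcher = DictionaryMatcher(
            (d.name for d in res.drug_lexicon), PLAIN_WORD_CHARS
        )
        self._drug_canonical = {d.name.lower(): d.name for d in res.drug_lexicon}
        cue_unigrams = {s for s in res.label_lexicon.positive | res.label_lexicon.negative
                        if " " not in s}
        self.lemmatizer = Lemmatizer(cue_unigrams | set(res.verb_polarity.classes))
        # the root finder lemmatizes down to polarity *lemmas*, so its known
        # vocabulary must not contain inflected cue surfaces
        self.root_finder = HeuristicRootFinder(res.verb_polarity.classes)
        if self.ner_backend is None:
            self.ner_backend = GazetteerNerBackend(
                res.population_tables.default_norp_vocabulary()
            )

    # ------------------------------------------------------------------
    def run(self, records: Sequence[AbstractRecord]) -> PipelineResult:
        annotations: dict[str, list[SentenceAnnotation]] = {}
        categories: dict[str, set[StudyCategory]] = {}
        populations: dict[str, list[PopulationTag]] = {}
        screened: list[str] = []
        from hlalit.taggers import tag_populations  # local to avoid cycle noise

        for record in records:
            if not screen_abstract(record, self.allele_matcher, self.disease_matcher):
                continue
            screened.append(record.pmid)
            anns = self.annotate_record(record)
            annotations[record.pmid] = anns
            categories[record.pmid] = categorize_abstract(
                anns,
                self.resources.disease_lexicon,
                adr_tree_prefixes=self.adr_tree_prefixes,
                exclusive=self.exclusive_categories,
            )
            populations[record.pmid] = tag_populations(
                record, self.ner_backend, self.resources.population_tables
            )
        return PipelineResult(
            records=list(records),
            screened_pmids=screened,
            annotations=annotations,
            categories=categories,
            populations=populations,
        )

    # ------------------------------------------------------------------
    def annotate_record(self, record: AbstractRecord) -> list[SentenceAnnotation]:
        """Retained (allele+disease co-mention) sentences, fully annotated."""
        res = self.resources
        candidates = []
        for sentence in sentence_split(record):
            mentions: list[Mention] = []
            mentions += match_alleles(sentence, res.allele_map, self.allele_matcher)
            mentions += match_diseases(sentence, res.disease_lexicon, self.disease_matcher)
            candidates.append(SentenceAnnotation(sentence=sentence, mentions=mentions))
        retained = filter_cooccurrence_sentences(candidates)
        for ann in retained:
            ann.mentions = _drop_cross_kind_overlaps(ann.mentions)
            ann.mentions += tag_drugs(
                ann.sentence,
                self.drug_matcher,
                ann.mentions_of(MentionKind.DISEASE),
                self._drug_canonical,
            )
            for rsid in tag_snps(ann.sentence.text):
                pos = ann.sentence.text.lower().find(rsid)
                ann.mentions.append(
                    Mention(
                        kind=MentionKind.SNP,
                        surface=ann.sentence.text[pos : pos + len(rsid)],
                        canonical=rsid,
                        char_start=pos,
                        char_end=pos + len(rsid),
                    )
                )
            ann.coding = detect_labels(
                ann.sentence, ann.mentions, res.label_lexicon, self.lemmatizer, self.guard_k
            )
            ann.stage1 = code_to_stage1_label(ann.coding)
            masked = mask_entities(ann.sentence, ann.mentions)
            ann.root_verb, ann.verb_class = root_verb(
                masked, res.verb_polarity, self.root_finder
            )
            ann.final_label = annotate_sentence(ann.stage1, ann.verb_class)
        return retained


def _drop_cross_kind_overlaps(mentions: list[Mention]) -> list[Mention]:
    """Longest-match resolution across allele/disease mentions so masking
    sees non-overlapping spans (within-kind overlaps are already resolved)."""
    ordered = sorted(mentions, key=lambda m: (m.char_start, -(m.char_end - m.char_start)))
    out: list[Mention] = []
    last_end = -1
    for m in ordered:
        if m.char_start >= last_end:
            out.append(m)
            last_end = m.char_end
    return out
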