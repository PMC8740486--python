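"""Core domain types shared across the pipeline.

Offsets are 0-based half-open everywhere: a span ``(start, end)`` over text
``t`` denotes ``t[start:end]``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


@dataclass
class AbstractRecord:
    """One parsed PubMed citation.

    ``abstract_text`` holds the cleaned abstract (structured-abstract
    subheading labels removed); sentence offsets refer to this string.
    """

    pmid: str
    title: str
    abstract_text: str
    pub_date: str  # ISO date, possibly year-only ("1999") or year-month
    journal: str
    article_types: list[str] = field(default_factory=list)
    authors: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class Sentence:
    """A sentence of a cleaned abstract with offsets into it."""

    record_pmid: str
    index: int
    text: str
    char_start: int
    char_end: int

    def __post_init__(self) -> None:
        if self.char_end - self.char_start != len(self.text):
            raise ValueError(
                f"span ({self.char_start},{self.char_end}) does not fit text "
                f"of length {len(self.text)}"
            )


class MentionKind(str, enum.Enum):
    ALLELE = "allele"
    DISEASE = "disease"
    DRUG = "drug"
    SNP = "snp"
    POPULATION = "population"


@dataclass(frozen=True)
class Mention:
    """An entity mention anchored to original-sentence offsets.

    ``canonical`` is the normalized identifier: the current IMGT-style allele
    name, a MeSH descriptor ID, a drug name, or an rsID.  ``search_variant``
    records which preprocessed search text produced the hit ("A" keeps
    special characters, "B" removes them).
    """

    kind: MentionKind
    surface: str
    canonical: str
    char_start: int
    char_end: int
    search_variant: str = "A"
    ambiguous: bool = False
    candidates: tuple[str, ...] = ()

    @property
    def span(self) -> tuple[int, int]:
        return (self.char_start, self.char_end)


@dataclass(frozen=True)
class PopulationTag:
    """A population/ethnicity mention found anywhere in an abstract."""

    surface: str
    normalized: str
    bin: str  # "country" | "ethnic_group" | "unbinned"


@dataclass(frozen=True)
class CodingVector:
    """Per-sentence presence bits for positive, negative and negation cues."""

    has_pos: bool
    has_neg: bool
    has_negation: bool

    def as_tuple(self) -> tuple[int, int, int]:
        return (int(self.has_pos), int(self.has_neg), int(self.has_negation))


class Stage1Label(str, enum.Enum):
    """Label assigned from the coding vector alone (n-gram stage)."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    NEGATION = "negation"
    COMPLEX = "complex"
    AMBIGUOUS = "ambiguous"
    OTHERS = "others"


class VerbClass(str, enum.Enum):
    """Polarity class of a sentence's root verb."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    INVESTIGATORY = "investigatory"
    UNKNOWN = "unknown"


class SentenceLabel(str, enum.Enum):
    """Final semantic label of an allele-disease co-occurrence sentence."""

    POSITIVE = "Positive"
    NEGATIVE = "Negative"
    COMPLEX = "Complex"
    AMBIGUOUS = "Ambiguous"
    INVESTIGATORY = "Investigatory"
    OTHERS = "Others"


class StudyCategory(str, enum.Enum):
    """Broad study category of an abstract (an abstract may carry several)."""

    DISEASES = "Diseases"
    TRANSPLANTATION = "Transplantation"
    SIGNS_SYMPTOMS = "SignsSymptoms"
    THERAPEUTICS_ADR = "TherapeuticsADR"


@dataclass
class SentenceAnnotation:
    """A sentence with its mentions, coding vector and semantic labels."""

    sentence: Sentence
    mentions: list[Mention] = field(default_factory=list)
    coding: CodingVector | None = None
    stage1: Stage1Label | None = None
    root_verb: str = ""
    verb_class: VerbClass = VerbClass.UNKNOWN
    final_label: SentenceLabel | None = None

    def mentions_of(self, kind: MentionKind) -> list[Mention]:
        return [m for m in self.mentions if m.kind == kind]
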