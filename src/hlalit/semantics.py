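"""Hybrid sentence-polarity labeling.

Stage 1 scans a sentence for positive / negative / negation cue phrases
(curated from POS-filtered verb/adverb n-grams) into a three-bit coding
vector, mapped to a stage-1 label.  Stage 2 masks entity mentions
(@GENE/@DISEASE), finds the root verb, and combines both signals into one of
six final classes: Positive, Negative, Complex, Ambiguous, Investigatory,
Others.

A carrier-status guard keeps "HLA-B27 negative" (absence of the allele in
carriers) from being read as a negative *association*: the tokens
"positive"/"negative" within ``guard_k`` tokens after an allele mention are
never association cues.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Protocol, Sequence

from hlalit.text import Lemmatizer, PosTagger, Token, tokenize
from hlalit.types import (
    CodingVector,
    Mention,
    MentionKind,
    Sentence,
    SentenceLabel,
    Stage1Label,
    VerbClass,
)

DEFAULT_NEGATION = frozenset({"not", "none", "no"})
GUARD_TOKENS = frozenset({"positive", "negative"})


def _data_text(name: str) -> str:
    return resources.files("hlalit.data").joinpath(name).read_text(encoding="utf-8")


# ---------------------------------------------------------------------------
# Lexicons
# ---------------------------------------------------------------------------

@dataclass
class LabelLexicon:
    """Positive/negative association-cue surfaces plus negation words."""

    positive: frozenset[str]
    negative: frozenset[str]
    negation: frozenset[str] = DEFAULT_NEGATION

    def __post_init__(self) -> None:
        if self.positive & self.negative:
            raise ValueError("positive and negative label sets overlap")

    @property
    def max_ngram(self) -> int:
        return max(
            (s.count(" ") + 1 for s in self.positive | self.negative), default=1
        )

    @classmethod
    def from_tsv(cls, path: str, negation: Iterable[str] = DEFAULT_NEGATION) -> "LabelLexicon":
        return cls._parse(open(path, encoding="utf-8").read(), negation)

    @classmethod
    def load_default(cls) -> "LabelLexicon":
        """The shipped cue table (synthetic reconstruction; 1107 positive,
        20 negative surfaces, matching the published counts)."""
        return cls._parse(_data_text("label_lexicon_synthetic.tsv"), DEFAULT_NEGATION)

    @classmethod
    def _parse(cls, text: str, negation: Iterable[str]) -> "LabelLexicon":
        pos: set[str] = set()
        neg: set[str] = set()
        for line in text.splitlines():
            if not line.strip() or line.startswith("surface\t"):
                continue
            surface, _, polarity = line.partition("\t")
            polarity = polarity.strip().lower()
            if polarity == "positive":
                pos.add(surface.strip().lower())
            elif polarity == "negative":
                neg.add(surface.strip().lower())
            else:
                raise ValueError(f"bad polarity {polarity!r} for {surface!r}")
        return cls(frozenset(pos), frozenset(neg), frozenset(w.lower() for w in negation))


@dataclass
class VerbPolarity:
    """Root-verb lemma -> polarity class (positive/negative/investigatory)."""

    classes: dict[str, VerbClass] = field(default_factory=dict)

    def lookup(self, lemma: str) -> VerbClass:
        return self.classes.get(lemma.lower(), VerbClass.UNKNOWN)

    @classmethod
    def from_tsv(cls, path: str) -> "VerbPolarity":
        return cls._parse(open(path, encoding="utf-8").read())

    @classmethod
    def load_default(cls) -> "VerbPolarity":
        return cls._parse(_data_text("verb_polarity.tsv"))

    @classmethod
    def _parse(cls, text: str) -> "VerbPolarity":
        classes: dict[str, VerbClass] = {}
        for line in text.splitlines():
            if not line.strip() or line.startswith("lemma\t"):
                continue
            lemma, _, klass = line.partition("\t")
            classes[lemma.strip().lower()] = VerbClass(klass.strip().lower())
        return cls(classes)


def load_default_stopwords() -> frozenset[str]:
    return frozenset(
        w.strip().lower() for w in _data_text("stopwords.txt").splitlines() if w.strip()
    )


# ---------------------------------------------------------------------------
# Stage 1: cue detection and coding vector
# ---------------------------------------------------------------------------

def detect_labels(
    sentence: Sentence,
    mentions: Sequence[Mention],
    lex: LabelLexicon,
    lemmatizer: Lemmatizer | None = None,
    guard_k: int = 2,
) -> CodingVector:
    """Scan one sentence for cue phrases and set the three presence bits.

    Matching is token-level over unigrams/bigrams/trigrams of both raw
    lowercased tokens and their lemmas.  The carrier-status guard excludes
    "positive"/"negative" tokens within ``guard_k`` tokens after an allele
    mention from cue matching (but they still block nothing else).
    """
    lemmatizer = lemmatizer or Lemmatizer(
        {s for s in lex.positive | lex.negative if " " not in s}
    )
    tokens = tokenize(sentence.text)
    blocked = _guarded_indices(tokens, mentions, guard_k)
    lowers = [t.lower for t in tokens]
    lemmas = [lemmatizer.lemma(t.lower) for t in tokens]
    has_pos = has_neg = has_negation = False
    max_n = min(lex.max_ngram, 3)
    for i in range(len(tokens)):
        if lowers[i] in lex.negation:
            has_negation = True
        for n in range(1, max_n + 1):
            j = i + n
            if j > len(tokens):
                break
            if any(k in blocked for k in range(i, j)):
                continue
            for form in (" ".join(lowers[i:j]), " ".join(lemmas[i:j])):
                if form in lex.positive:
                    has_pos = True
                elif form in lex.negative:
                    has_neg = True
    return CodingVector(has_pos, has_neg, has_negation)


def _guarded_indices(
    tokens: Sequence[Token], mentions: Sequence[Mention], guard_k: int
) -> set[int]:
    """Indices of "positive"/"negative" tokens within guard_k tokens after
    an allele mention (carrier-status usage, e.g. "HLA-B27 negative")."""
    allele_end_idx: list[int] = []
    for m in mentions:
        if m.kind != MentionKind.ALLELE:
            continue
        covered = [
            i for i, t in enumerate(tokens) if t.start < m.char_end and t.end > m.char_start
        ]
        if covered:
            allele_end_idx.append(max(covered))
    blocked: set[int] = set()
    for i, t in enumerate(tokens):
        if t.lower in GUARD_TOKENS and any(0 < i - j <= guard_k for j in allele_end_idx):
            blocked.add(i)
    return blocked


#: Total mapping from the 8 coding vectors to a stage-1 label.
STAGE1_TABLE: dict[tuple[int, int, int], Stage1Label] = {
    (0, 0, 0): Stage1Label.OTHERS,
    (1, 0, 0): Stage1Label.POSITIVE,
    (0, 1, 0): Stage1Label.NEGATIVE,
    (0, 0, 1): Stage1Label.NEGATION,
    (1, 1, 0): Stage1Label.COMPLEX,
    (1, 1, 1): Stage1Label.COMPLEX,
    (1, 0, 1): Stage1Label.AMBIGUOUS,
    (0, 1, 1): Stage1Label.AMBIGUOUS,
}


def code_to_stage1_label(v: CodingVector) -> Stage1Label:
    """Deterministic, total mapping of the binary layout to a stage-1 label:
    one polarity alone keeps its name; both polarities -> complex (negation
    does not rescue it); one polarity plus negation -> ambiguous; negation
    alone -> negation; nothing -> others."""
    return STAGE1_TABLE[v.as_tuple()]


# ---------------------------------------------------------------------------
# Stage 2: masking and root verb
# ---------------------------------------------------------------------------

MASK_TAGS = {MentionKind.ALLELE: "@GENE", MentionKind.DISEASE: "@DISEASE"}


def mask_entities(sentence: Sentence, mentions: Sequence[Mention]) -> str:
    """Replace allele mentions with @GENE and disease mentions with
    @DISEASE so multi-word entities stay single tokens for parsing.

    Mentions must be non-overlapping (guaranteed upstream by longest-match
    resolution); replacement runs right-to-left so earlier offsets stay
    valid.
    """
    maskable = sorted(
        (m for m in mentions if m.kind in MASK_TAGS), key=lambda m: m.char_start
    )
    for a, b in zip(maskable, maskable[1:]):
        if b.char_start < a.char_end:
            raise ValueError(
                f"overlapping mention spans {a.span} / {b.span} in {sentence.record_pmid}"
            )
    text = sentence.text
    for m in reversed(maskable):
        text = text[: m.char_start] + MASK_TAGS[m.kind] + text[m.char_end:]
    return text


class DependencyParser(Protocol):
    """Interface: return the root-verb lemma of a sentence, or None."""

    def root_verb(self, text: str) -> str | None: ...


class HeuristicRootFinder:
    """Flat POS-sequence fallback for the dependency parser.

    The first finite verb outside a to-infinitival purpose clause is treated
    as the root; a sentence opening with a purpose clause ("To investigate
    ...") roots at that infinitive.  Auxiliaries are skipped so "was
    associated with" roots at "associated".
    """

    def __init__(self, verb_lemmas: Iterable[str], lemmatizer: Lemmatizer | None = None):
        self.lemmatizer = lemmatizer or Lemmatizer(set(verb_lemmas))
        self.tagger = PosTagger(verb_lemmas, self.lemmatizer)

    def root_verb(self, text: str) -> str | None:
        lemma, _ = self.root_verb_with_context(text)
        return lemma or None

    def root_verb_with_context(self, text: str) -> tuple[str, bool]:
        """(root lemma or "", opened-with-purpose-clause flag)."""
        tokens = tokenize(text)
        if not tokens:
            return "", False
        if tokens[0].lower == "to" and len(tokens) > 1:
            cand = tokens[1].lower
            if self.tagger.tag(cand) == "VERB":
                # to-infinitival purpose-clause opener: root at the infinitive
                return self.lemmatizer.lemma(cand), True
        for t in tokens:
            if self.tagger.tag(t.lower) == "VERB":
                return self.lemmatizer.lemma(t.lower), False
        return "", False


def root_verb(
    masked: str,
    verb_polarity: VerbPolarity,
    parser: DependencyParser | None = None,
) -> tuple[str, VerbClass]:
    """Root-verb lemma of a masked sentence and its polarity class.

    A lemma missing from the polarity lexicon is "unknown", except that a
    to-infinitival purpose-clause opener defaults to investigatory (its
    pragmatic function is to state a study aim).
    """
    if parser is None:
        parser = HeuristicRootFinder(verb_polarity.classes)
    if isinstance(parser, HeuristicRootFinder):
        lemma, purpose = parser.root_verb_with_context(masked)
    else:
        try:
            lemma = parser.root_verb(masked) or ""
        except Exception:
            return "", VerbClass.UNKNOWN
        purpose = masked.lower().lstrip().startswith("to ")
    if not lemma:
        return "", VerbClass.UNKNOWN
    klass = verb_polarity.lookup(lemma)
    if klass is VerbClass.UNKNOWN and purpose:
        klass = VerbClass.INVESTIGATORY
    return lemma, klass


# ---------------------------------------------------------------------------
# Final decision table
# ---------------------------------------------------------------------------

def annotate_sentence(stage1: Stage1Label, verb_class: VerbClass) -> SentenceLabel:
    """Combine the n-gram stage-1 label with the root-verb class.

    Agreement is required for a polar call: (positive, positive) -> Positive
    and (negative, negative) -> Negative.  Complex stays Complex; ambiguous
    and negation-only fold into Ambiguous; an investigatory verb turns any
    unresolved polarity (or none) into Investigatory; everything else --
    including stage-1/verb disagreement -- is Others.
    """
    if stage1 is Stage1Label.COMPLEX:
        return SentenceLabel.COMPLEX
    if stage1 in (Stage1Label.AMBIGUOUS, Stage1Label.NEGATION):
        return SentenceLabel.AMBIGUOUS
    if stage1 is Stage1Label.POSITIVE and verb_class is VerbClass.POSITIVE:
        return SentenceLabel.POSITIVE
    if stage1 is Stage1Label.NEGATIVE and verb_class is VerbClass.NEGATIVE:
        return SentenceLabel.NEGATIVE
    if verb_class is VerbClass.INVESTIGATORY:
        return SentenceLabel.INVESTIGATORY
    return SentenceLabel.OTHERS


# ---------------------------------------------------------------------------
# N-gram candidate harvesting (lexicon curation aid)
# ---------------------------------------------------------------------------

DEFAULT_POS_PATTERNS: dict[int, tuple[tuple[str, ...], ...]] = {
    1: (("VERB",), ("ADV",)),
    2: (("ADV", "VERB"),),
    3: (("ADV", "ADV", "VERB"), ("ADV", "VERB", "VERB")),
}


@dataclass
class NgramConfig:
    """Configuration for collocation harvesting.

    ``n_values`` must be a non-empty subset of {1, 2, 3}; ``freq_cutoff`` is
    the minimum corpus count for a candidate to surface (default 10).
    """

    n_values: frozenset[int] = frozenset({1, 2, 3})
    freq_cutoff: int = 10
    pos_patterns: dict[int, tuple[tuple[str, ...], ...]] = field(
        default_factory=lambda: dict(DEFAULT_POS_PATTERNS)
    )
    stopwords: frozenset[str] = field(default_factory=load_default_stopwords)

    def __post_init__(self) -> None:
        if not self.n_values or not self.n_values <= {1, 2, 3}:
            raise ValueError("n_values must be a non-empty subset of {1,2,3}")
        if self.freq_cutoff < 1:
            raise ValueError("freq_cutoff must be >= 1")


def build_ngram_candidates(
    sentences: Iterable[str],
    cfg: NgramConfig,
    tagger: PosTagger,
    lemmatizer: Lemmatizer | None = None,
) -> list[tuple[str, int]]:
    """Frequency-ranked verb/adverb collocation candidates for manual
    curation into the label lexicon.

    Tokens are lowercased, stopword-filtered and lemmatized; n-grams are
    kept when their POS-tag sequence matches a configured pattern and their
    corpus count reaches ``freq_cutoff``.  Sorted by descending count, ties
    lexicographic.
    """
    lemmatizer = lemmatizer or tagger.lemmatizer
    counts: Counter[str] = Counter()
    for text in sentences:
        toks = [t.lower for t in tokenize(text) if t.lower not in cfg.stopwords]
        tags = [tagger.tag(t) for t in toks]
        lemmas = [lemmatizer.lemma(t) for t in toks]
        for n in sorted(cfg.n_values):
            patterns = cfg.pos_patterns.get(n, ())
            for i in range(len(toks) - n + 1):
                if tuple(tags[i : i + n]) in patterns:
                    counts[" ".join(lemmas[i : i + n])] += 1
    ranked = [(g, c) for g, c in counts.items() if c >= cfg.freq_cutoff]
    ranked.sort(key=lambda gc: (-gc[1], gc[0]))
    return ranked
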