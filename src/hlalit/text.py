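"""Rule-based text utilities: tokenization, sentence splitting, lemmatization,
a part-of-speech heuristic, and the dual search-text preprocessing.

All components behind which a statistical model could sit (sentence splitter,
lemmatizer, POS layer) are deliberately rule-based and dependency-free so the
core pipeline runs offline; each is replaceable through a small interface.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Protocol

# Characters treated as "special" when building search variant B.  The hyphen
# is normalized to a space (Stevens-Johnson -> stevens johnson); the rest are
# deleted (Graves' -> graves, B(*)1301 -> b1301).
SPECIAL_TO_SPACE = "-−‐‑"  # ASCII hyphen + unicode minus/hyphens
SPECIAL_TO_DELETE = "'()*:’"

_TOKEN_RE = re.compile(r"[A-Za-z0-9@](?:[A-Za-z0-9@*:'’-]*[A-Za-z0-9@*])?")


@dataclass(frozen=True)
class Token:
    text: str
    start: int
    end: int

    @property
    def lower(self) -> str:
        return self.text.lower()


def tokenize(text: str) -> list[Token]:
    """Word-tokenize, keeping offsets.

    Hyphens, apostrophes, '*' and ':' are token-internal so allele names
    (HLA-B*13:01), masked tags (@GENE) and hyphenated compounds
    (carbamazepine-induced) each stay one token.
    """
    return [Token(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


# ---------------------------------------------------------------------------
# Sentence splitting
# ---------------------------------------------------------------------------

class SentenceSplitter(Protocol):
    """Interface: return (start, end) spans of sentences in `text`."""

    def split(self, text: str) -> list[tuple[int, int]]: ...


#: Abbreviations after which a period never ends a sentence.
ABBREVIATIONS = {
    "al", "spp", "sp", "e.g", "i.e", "etc", "vs", "cf", "fig", "figs",
    "dr", "prof", "st", "no", "approx", "ca", "resp", "ref", "refs",
    "viz", "mr", "mrs", "ms", "inc", "ltd",
}


class RuleSentenceSplitter:
    """Period/question/exclamation splitter with an abbreviation exception
    list and guards for initials and decimal numbers.

    A candidate boundary is a sentence-final character ([.!?]) followed by
    whitespace and an uppercase letter, digit or quote.  Candidates are
    rejected when the period terminates a known abbreviation, a single
    capital initial ("J. Smith") or sits between digits (3.5).
    """

    def __init__(self, abbreviations: Iterable[str] | None = None) -> None:
        self.abbreviations = {
            a.lower().rstrip(".") for a in (abbreviations or ABBREVIATIONS)
        }

    def split(self, text: str) -> list[tuple[int, int]]:
        if not text.strip():
            return []
        boundaries: list[int] = []
        for m in re.finditer(r"[.!?]+(?=\s+[\"'(]?[A-Z0-9])", text):
            end = m.end()
            if m.group().endswith(".") or m.group() == ".":
                word = self._word_before(text, m.start())
                if word is not None:
                    w = word.lower()
                    if w in self.abbreviations or w.rstrip(".") in self.abbreviations:
                        continue
                    # single-letter initial: "J." in author names
                    if len(word) == 1 and word.isupper():
                        continue
            boundaries.append(end)
        spans: list[tuple[int, int]] = []
        start = 0
        for b in boundaries + [len(text)]:
            seg = text[start:b]
            lstrip = len(seg) - len(seg.lstrip())
            rstrip = len(seg) - len(seg.rstrip())
            if seg.strip():
                spans.append((start + lstrip, b - rstrip))
            start = b
        return spans

    @staticmethod
    def _word_before(text: str, period_pos: int) -> str | None:
        m = re.search(r"([A-Za-z][A-Za-z.]*)$", text[:period_pos])
        return m.group(1) if m else None


# ---------------------------------------------------------------------------
# Lemmatization (rule-based suffix stripping)
# ---------------------------------------------------------------------------

_IRREGULAR_NOUNS = {
    "men": "man", "women": "woman", "children": "child", "people": "person",
    "feet": "foot", "teeth": "tooth", "mice": "mouse", "geese": "goose",
    "analyses": "analysis", "diagnoses": "diagnosis", "hypotheses": "hypothesis",
    "criteria": "criterion", "phenomena": "phenomenon",
}

_IRREGULAR_VERBS = {
    "was": "be", "were": "be", "is": "be", "are": "be", "been": "be",
    "being": "be", "am": "be", "has": "have", "had": "have", "having": "have",
    "did": "do", "does": "do", "done": "do", "found": "find", "shown": "show",
    "showed": "show", "seen": "see", "saw": "see", "gave": "give",
    "given": "give", "underwent": "undergo", "undergone": "undergo",
}


def singularize(word: str) -> str:
    """Singular form of a plural noun; identity on non-plurals."""
    w = word.lower()
    if w in _IRREGULAR_NOUNS:
        return _IRREGULAR_NOUNS[w]
    if len(w) > 4 and w.endswith("ies"):
        return w[:-3] + "y"
    # drop "es" only when it was added for a sibilant stem (viruses, churches);
    # otherwise "diseases" would lose its final e
    if len(w) > 3 and w.endswith("es") and w[:-2].endswith(
        ("ss", "us", "is", "x", "z", "ch", "sh")
    ):
        return w[:-2]
    if len(w) > 3 and w.endswith("oes"):
        return w[:-2]
    if w.endswith("s") and not w.endswith(("ss", "us", "is")):
        return w[:-1]
    return w


def pluralize(word: str) -> str:
    """Regular plural of a noun (s/es/ies rules + irregular table)."""
    w = word.lower()
    inv = {v: k for k, v in _IRREGULAR_NOUNS.items()}
    if w in inv:
        return inv[w]
    if len(w) > 2 and w.endswith("y") and w[-2] not in "aeiou":
        return w[:-1] + "ies"
    if w.endswith(("s", "x", "z", "ch", "sh")):
        return w + "es"
    return w + "s"


class Lemmatizer:
    """Suffix-stripping lemmatizer seeded with a known-lemma vocabulary.

    Verb inflections (-s, -ed, -ing, -ies/-ied) are stripped with
    e-restoration and consonant-doubling undone only when the candidate base
    is in ``known_lemmas``; otherwise the noun singularizer applies.  Good
    enough to collapse "associated/associates/associating" -> "associate"
    without a model.
    """

    def __init__(self, known_lemmas: Iterable[str] = ()) -> None:
        self.known = {w.lower() for w in known_lemmas}

    def lemma(self, word: str) -> str:
        w = word.lower()
        if w in _IRREGULAR_VERBS:
            return _IRREGULAR_VERBS[w]
        if w in self.known:
            return w
        for cand in self._verb_candidates(w):
            if cand in self.known:
                return cand
        return singularize(w)

    @staticmethod
    def _verb_candidates(w: str) -> list[str]:
        out: list[str] = []
        if w.endswith("ies") and len(w) > 4:
            out.append(w[:-3] + "y")
        if w.endswith("ied") and len(w) > 4:
            out.append(w[:-3] + "y")
        if w.endswith("ing") and len(w) > 4:
            stem = w[:-3]
            out += [stem, stem + "e"]
            if len(stem) > 2 and stem[-1] == stem[-2]:
                out.append(stem[:-1])
        if w.endswith("ed") and len(w) > 3:
            stem = w[:-2]
            out += [w[:-1], stem]  # associated -> associate; linked -> link
            if len(stem) > 2 and stem[-1] == stem[-2]:
                out.append(stem[:-1])
        if w.endswith("es") and len(w) > 3:
            out += [w[:-1], w[:-2]]
        elif w.endswith("s") and len(w) > 2:
            out.append(w[:-1])
        return out


# ---------------------------------------------------------------------------
# POS heuristic
# ---------------------------------------------------------------------------

AUXILIARIES = {
    "is", "are", "was", "were", "be", "been", "being", "am",
    "has", "have", "had", "having", "do", "does", "did",
    "can", "could", "may", "might", "will", "would", "shall", "should", "must",
}

#: -ly words that are not adverbs.
_NOT_ADVERBS = {
    "family", "italy", "july", "anomaly", "assembly", "supply", "monopoly",
    "apply", "imply", "reply", "rely", "fly", "only",
}

#: Closed list of non -ly adverbs relevant to association phrasing.
_PLAIN_ADVERBS = {
    "very", "quite", "rather", "most", "more", "less", "least", "well",
    "often", "always", "never", "also", "however", "together", "further",
}


class PosTagger:
    """Tiny POS layer distinguishing VERB / ADV / AUX / OTHER.

    Verbs are recognized against a lemma vocabulary (via the lemmatizer) plus
    inflectional morphology; adverbs by the -ly rule plus a closed list.  This
    is intentionally a coarse filter for collocation harvesting, not a parser.
    """

    def __init__(self, verb_lemmas: Iterable[str], lemmatizer: Lemmatizer | None = None) -> None:
        self.verb_lemmas = {v.lower() for v in verb_lemmas}
        self.lemmatizer = lemmatizer or Lemmatizer(self.verb_lemmas)

    def tag(self, token: str) -> str:
        w = token.lower()
        if w in AUXILIARIES:
            return "AUX"
        if (w.endswith("ly") and len(w) > 3 and w not in _NOT_ADVERBS) or w in _PLAIN_ADVERBS:
            return "ADV"
        if self.lemmatizer.lemma(w) in self.verb_lemmas or w in self.verb_lemmas:
            return "VERB"
        return "OTHER"


# ---------------------------------------------------------------------------
# Search-text preprocessing (variant A / variant B)
# ---------------------------------------------------------------------------

@dataclass
class SearchText:
    """Lowercased search variants of a sentence with offset maps.

    * variant A: lowercased original; positions map 1:1.
    * variant B: lowercased with special characters removed -- hyphens become
      spaces, apostrophes/parentheses/'*'/':' are deleted, runs of whitespace
      collapse to one space.  ``map_b[i]`` is the original-character offset
      of ``text_b[i]`` (for inserted spaces: the offset of the character that
      produced the space).
    """

    original: str
    text_a: str
    text_b: str
    map_b: list[int]

    def span_b_to_original(self, start: int, end: int) -> tuple[int, int]:
        """Map a half-open span of variant B back to original offsets."""
        if start >= end:
            raise ValueError("empty span")
        return (self.map_b[start], self.map_b[end - 1] + 1)


def preprocess_variants(text: str) -> SearchText:
    """Build both lowercased search variants of a sentence.

    Keeping variant A (specials intact) alongside variant B widens the search
    space so that e.g. both "Stevens-Johnson syndrome" and "Stevens Johnson
    syndrome", "Graves' disease" and "Graves disease" are matchable.
    """
    text_a = text.lower()
    chars: list[str] = []
    mapping: list[int] = []
    prev_space = True  # suppress leading space
    for i, ch in enumerate(text_a):
        if ch in SPECIAL_TO_DELETE:
            continue
        if ch in SPECIAL_TO_SPACE or ch.isspace():
            if prev_space:
                continue
            chars.append(" ")
            mapping.append(i)
            prev_space = True
            continue
        chars.append(ch)
        mapping.append(i)
        prev_space = False
    # drop trailing space
    if chars and chars[-1] == " ":
        chars.pop()
        mapping.pop()
    return SearchText(original=text, text_a=text_a, text_b="".join(chars), map_b=mapping)
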