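"""Dictionary NER: offset-anchored keyword matching over both search
variants, abstract screening and allele-disease co-occurrence filtering.

Matching is case-insensitive (the search variants are lowercased) and
boundary-aware: a hit must be flanked by characters outside the lexicon's
word-character class.  For alleles that class is ``[A-Za-z0-9*:]`` because
standard ``\\b`` semantics fail next to '*'.  Overlapping hits resolve
longest-match-wins with left-most tie-breaking.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

from hlalit.lexicons.diseases import DiseaseLexicon
from hlalit.lexicons.hla import AlleleSurfaceMap, normalize_allele
from hlalit.text import SearchText, preprocess_variants
from hlalit.types import AbstractRecord, Mention, MentionKind, Sentence, SentenceAnnotation

ALLELE_WORD_CHARS = "A-Za-z0-9*:"
PLAIN_WORD_CHARS = "A-Za-z0-9"


@dataclass(frozen=True)
class RawMatch:
    surface_key: str      # lexicon key that matched (lowercased)
    char_start: int       # offsets in the ORIGINAL sentence text
    char_end: int
    variant: str          # "A" or "B"


class DictionaryMatcher:
    """Compiled multi-keyword matcher over the A/B search variants.

    One alternation regex per variant, alternatives sorted longest-first so
    the scan is leftmost-longest; boundary enforcement via lookarounds on the
    configured word-character class.  Variant-B keys are the keyword's own
    specials-removed form, and hits are mapped back to original offsets
    through the position map.
    """

    def __init__(self, surfaces: Iterable[str], word_chars: str = PLAIN_WORD_CHARS) -> None:
        self.word_chars = word_chars
        keys_a = sorted({s.lower() for s in surfaces if s.strip()})
        self._re_a = self._compile(keys_a)
        b_index: dict[str, set[str]] = {}
        for k in keys_a:
            kb = preprocess_variants(k).text_b
            if kb:
                b_index.setdefault(kb, set()).add(k)
        self.b_to_a = {k: tuple(sorted(v)) for k, v in b_index.items()}
        self._re_b = self._compile(sorted(self.b_to_a))

    def _compile(self, keys: list[str]) -> re.Pattern | None:
        if not keys:
            return None
        alts = sorted(keys, key=len, reverse=True)
        wc = self.word_chars
        return re.compile(
            rf"(?<![{wc}])(?:{'|'.join(re.escape(k) for k in alts)})(?![{wc}])"
        )

    def scan(self, st: SearchText) -> list[RawMatch]:
        """All boundary-valid hits mapped to original offsets, deduplicated
        by span (variant A preferred), overlaps resolved leftmost-longest."""
        hits: dict[tuple[int, int], RawMatch] = {}
        if self._re_a is not None:
            for m in self._re_a.finditer(st.text_a):
                hits[(m.start(), m.end())] = RawMatch(m.group(), m.start(), m.end(), "A")
        if self._re_b is not None:
            for m in self._re_b.finditer(st.text_b):
                span = st.span_b_to_original(m.start(), m.end())
                if span not in hits:
                    # report the first generating A-key for canonicalization
                    hits[span] = RawMatch(self.b_to_a[m.group()][0], span[0], span[1], "B")
        return resolve_overlaps(sorted(hits.values(), key=lambda h: (h.char_start, -(h.char_end - h.char_start))))


def resolve_overlaps(matches: list[RawMatch]) -> list[RawMatch]:
    """Greedy leftmost-longest selection of non-overlapping matches.

    Input must be sorted by (start, -length).
    """
    out: list[RawMatch] = []
    last_end = -1
    for m in matches:
        if m.char_start >= last_end:
            out.append(m)
            last_end = m.char_end
    return out


def match_diseases(sentence: Sentence, lexicon: DiseaseLexicon,
                   matcher: DictionaryMatcher | None = None) -> list[Mention]:
    """Disease-keyword mentions in one sentence (both search variants)."""
    matcher = matcher or DictionaryMatcher(lexicon.surface_index, PLAIN_WORD_CHARS)
    st = preprocess_variants(sentence.text)
    out: list[Mention] = []
    for h in matcher.scan(st):
        entry = lexicon.lookup(h.surface_key)
        if entry is None:
            continue
        out.append(
            Mention(
                kind=MentionKind.DISEASE,
                surface=sentence.text[h.char_start:h.char_end],
                canonical=entry.mesh_id,
                char_start=h.char_start,
                char_end=h.char_end,
                search_variant=h.variant,
            )
        )
    return out


def match_alleles(sentence: Sentence, surface_map: AlleleSurfaceMap,
                  matcher: DictionaryMatcher | None = None) -> list[Mention]:
    """HLA-allele mentions; boundary class ``[A-Za-z0-9*:]``."""
    matcher = matcher or DictionaryMatcher(surface_map.surfaces, ALLELE_WORD_CHARS)
    st = preprocess_variants(sentence.text)
    out: list[Mention] = []
    for h in matcher.scan(st):
        try:
            norm = normalize_allele(h.surface_key, surface_map)
        except LookupError:
            continue
        out.append(
            Mention(
                kind=MentionKind.ALLELE,
                surface=sentence.text[h.char_start:h.char_end],
                canonical=norm.canonical,
                char_start=h.char_start,
                char_end=h.char_end,
                search_variant=h.variant,
                ambiguous=norm.ambiguous,
                candidates=norm.candidates if norm.ambiguous else (),
            )
        )
    return out


def _contains_any(text: str, matcher: DictionaryMatcher) -> bool:
    return bool(matcher.scan(preprocess_variants(text)))


def screen_abstract(
    record: AbstractRecord,
    allele_matcher: DictionaryMatcher,
    disease_matcher: DictionaryMatcher,
) -> bool:
    """Keep an abstract iff title+text jointly mention >=1 allele surface
    and >=1 disease keyword (each may sit in either location)."""
    joint = record.title + "\n" + record.abstract_text
    return _contains_any(joint, allele_matcher) and _contains_any(joint, disease_matcher)


def filter_cooccurrence_sentences(
    annotations: Iterable[SentenceAnnotation],
) -> list[SentenceAnnotation]:
    """Retain sentences with >=1 allele and >=1 disease mention."""
    return [
        a
        for a in annotations
        if a.mentions_of(MentionKind.ALLELE) and a.mentions_of(MentionKind.DISEASE)
    ]
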