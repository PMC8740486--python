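"""Secondary entity taggers: SNP rsIDs, drugs (with false-positive
suppression against disease spans) and population/ethnicity mentions.

The population tagger runs over the whole abstract, not just co-occurrence
sentences, because cohort descriptions rarely share a sentence with the
allele-disease statement.  Its token-classification backend is injected; the
default is a gazetteer over the curated country/ethnic-group tables, so the
pipeline needs no model download.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Protocol, Sequence

from hlalit.matching import DictionaryMatcher, PLAIN_WORD_CHARS
from hlalit.text import preprocess_variants, singularize
from hlalit.types import AbstractRecord, Mention, MentionKind, PopulationTag, Sentence

logger = logging.getLogger(__name__)

#: Case-insensitive "rs" followed by at least two digits; no upper bound.
RSID_RE = re.compile(r"[rR][sS][0-9]{2,}")


def tag_snps(text: str) -> list[str]:
    """dbSNP rsIDs in order of first occurrence, lowercased, deduplicated.

    >>> tag_snps("RS12, rs345, rs12")
    ['rs12', 'rs345']
    """
    out: list[str] = []
    for m in RSID_RE.finditer(text):
        rsid = m.group().lower()
        if rsid not in out:
            out.append(rsid)
    return out


def tag_drugs(
    sentence: Sentence,
    drug_matcher: DictionaryMatcher,
    disease_mentions: Sequence[Mention],
    canonical_names: Mapping[str, str] | None = None,
) -> list[Mention]:
    """Drug mentions with the disease-containment false-positive filter.

    A drug hit whose span lies fully inside a disease-mention span is a
    fragment of the disease name ("insulin" inside "insulin dependent
    diabetes mellitus") and is discarded.
    """
    st = preprocess_variants(sentence.text)
    disease_spans = [(d.char_start, d.char_end) for d in disease_mentions]
    out: list[Mention] = []
    for h in drug_matcher.scan(st):
        if any(h.char_start >= s and h.char_end <= e for s, e in disease_spans):
            continue
        canonical = (canonical_names or {}).get(h.surface_key, h.surface_key)
        out.append(
            Mention(
                kind=MentionKind.DRUG,
                surface=sentence.text[h.char_start:h.char_end],
                canonical=canonical,
                char_start=h.char_start,
                char_end=h.char_end,
                search_variant=h.variant,
            )
        )
    return out


def build_drug_matcher(names: Iterable[str]) -> DictionaryMatcher:
    return DictionaryMatcher(names, PLAIN_WORD_CHARS)


# ---------------------------------------------------------------------------
# Populations
# ---------------------------------------------------------------------------

class NerBackend(Protocol):
    """Token-classification interface: (surface, label) entities over text.

    Labels follow the NORP/GPE convention: NORP for nationalities and
    ethno-religious groups, GPE for geo-political places.
    """

    def entities(self, text: str) -> list[tuple[str, str]]: ...


class GazetteerNerBackend:
    """Dictionary NER over curated demonym/ethnic-group (NORP) and place
    (GPE) vocabularies; the offline default backend."""

    def __init__(self, norp_terms: Iterable[str], gpe_terms: Iterable[str] = ()) -> None:
        self._norp = self._compile(norp_terms)
        self._gpe = self._compile(gpe_terms)

    @staticmethod
    def _compile(terms: Iterable[str]) -> re.Pattern | None:
        keys = sorted({t.strip().lower() for t in terms if t.strip()}, key=len, reverse=True)
        if not keys:
            return None
        return re.compile(
            r"(?<![A-Za-z0-9])(?:%s)(?![A-Za-z0-9])" % "|".join(re.escape(k) for k in keys),
            re.IGNORECASE,
        )

    def entities(self, text: str) -> list[tuple[str, str]]:
        out: list[tuple[str, str]] = []
        for label, pattern in (("NORP", self._norp), ("GPE", self._gpe)):
            if pattern is None:
                continue
            for m in pattern.finditer(text):
                out.append((m.group(), label))
        return out


@dataclass
class PopulationTables:
    """Curated binning tables: demonym -> country, plus ethnic-group names."""

    countries: Mapping[str, str]       # lowercased demonym -> country name
    ethnic_groups: frozenset[str]      # lowercased group names

    def default_norp_vocabulary(self) -> list[str]:
        plurals = [d + "s" for d in self.countries] + [e + "s" for e in self.ethnic_groups]
        return sorted(set(self.countries) | self.ethnic_groups | set(plurals))


def tag_populations(
    record: AbstractRecord,
    backend: NerBackend | None,
    tables: PopulationTables,
) -> list[PopulationTag]:
    """Population/ethnicity tags for a whole abstract.

    Only NORP-labelled entities are kept -- GPE output over biomedical text
    is dominated by organism names misread as places.  Surfaces are
    case-folded, singularized and deduplicated, then binned through the
    curated tables; unmapped surfaces come back flagged "unbinned".  A
    missing or failing backend degrades to an empty tag list.
    """
    if backend is None:
        logger.warning("population NER backend unavailable; skipping %s", record.pmid)
        return []
    text = record.title + "\n" + record.abstract_text
    try:
        entities = backend.entities(text)
    except Exception:  # backend failure must not kill the pipeline
        logger.warning("population NER backend failed on %s", record.pmid, exc_info=True)
        return []
    tags: list[PopulationTag] = []
    seen: set[str] = set()
    for surface, label in entities:
        if label != "NORP":
            continue
        norm = singularize(surface.lower())
        if norm in seen:
            continue
        seen.add(norm)
        if norm in tables.countries:
            tags.append(PopulationTag(surface=norm.capitalize(),
                                      normalized=tables.countries[norm], bin="country"))
        elif norm in tables.ethnic_groups:
            tags.append(PopulationTag(surface=norm.capitalize(),
                                      normalized=norm.capitalize(), bin="ethnic_group"))
        else:
            tags.append(PopulationTag(surface=norm.capitalize(),
                                      normalized=norm.capitalize(), bin="unbinned"))
    return tags
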