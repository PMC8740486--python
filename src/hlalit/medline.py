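"""MEDLINE/PubMed XML parsing, subheading stripping and sentence splitting.

Reads the PubMed baseline/updatefiles dialect (``PubmedArticle`` /
``MedlineCitation`` elements) with :mod:`lxml`, keeps only records carrying
the full metadata set (PMID, title, abstract, publication date, journal,
article type; authors optionally), and exposes offset-tracked sentence
splitting over the cleaned abstract.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import IO, Iterable

from lxml import etree

from hlalit.text import RuleSentenceSplitter, SentenceSplitter
from hlalit.types import AbstractRecord, Sentence

#: Structured-abstract section labels removed from abstract text.
SUBHEADING_LABELS = (
    "background",
    "introduction",
    "objective",
    "method",
    "experimental design",
    "result",
    "discussion",
    "importance",
    "setting",
    "design",
    "study objective",
    "patients",
    "participants",
    "conclusion",
)

# Label at start of text / line or right after a sentence terminator,
# optional plural, then a colon.  Case-insensitive.
_label_alt = "|".join(
    sorted((re.escape(l) for l in SUBHEADING_LABELS), key=len, reverse=True)
)
_SUBHEADING_RE = re.compile(
    rf"(?:(?<=^)|(?<=\n)|(?<=[.!?:;]\s))\s*(?:{_label_alt})e?s?\s*:\s*",
    re.IGNORECASE,
)


def strip_subheadings(text: str) -> str:
    """Remove structured-abstract labels ("BACKGROUND:", "RESULTS:" ...).

    Labels are matched case-insensitively, with optional plural, only at
    label positions (start of text/line or after a sentence boundary) and
    only when followed by a colon, so the ordinary noun "results" mid-sentence
    survives.  All other text is preserved verbatim.
    """
    return _SUBHEADING_RE.sub("", text).strip()


class MedlineParseError(ValueError):
    """Malformed MEDLINE XML; carries the reported parse position."""

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        super().__init__(message)
        self.line = line
        self.column = column


@dataclass
class ParseResult:
    """Records retained by :func:`parse_medline` plus the skip log."""

    records: list[AbstractRecord]
    skipped: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped)


REQUIRED_FIELDS = ("pmid", "title", "abstract", "pub_date", "journal", "article_types")


def parse_medline(
    source: str | IO[bytes],
    *,
    require_authors: bool = False,
) -> ParseResult:
    """Parse PubMed-dialect XML into :class:`AbstractRecord` objects.

    Records missing any required field (PMID, title, abstract text after
    subheading stripping, publication date, journal, article type — plus
    authors when ``require_authors``) are skipped and logged, not raised.
    Input order is preserved.

    Raises
    ------
    MedlineParseError
        On malformed XML, naming the parser-reported position.
    """
    try:
        tree = etree.parse(source)
    except etree.XMLSyntaxError as exc:
        line, column = (exc.position or (None, None))
        raise MedlineParseError(
            f"malformed MEDLINE XML at line {line}, column {column}: {exc.args[0]}",
            line=line,
            column=column,
        ) from exc

    records: list[AbstractRecord] = []
    skipped: list[tuple[str, tuple[str, ...]]] = []
    seen_pmids: set[str] = set()
    for article in tree.iter("PubmedArticle"):
        fields = _extract_fields(article)
        missing = [f for f in REQUIRED_FIELDS if not fields[f]]
        if require_authors and not fields["authors"]:
            missing.append("authors")
        if fields["pmid"] in seen_pmids:
            missing.append("pmid:duplicate")
        if missing:
            skipped.append((fields["pmid"] or "?", tuple(missing)))
            continue
        seen_pmids.add(fields["pmid"])
        records.append(
            AbstractRecord(
                pmid=fields["pmid"],
                title=fields["title"],
                abstract_text=fields["abstract"],
                pub_date=fields["pub_date"],
                journal=fields["journal"],
                article_types=fields["article_types"],
                authors=fields["authors"],
            )
        )
    return ParseResult(records=records, skipped=skipped)


_MONTHS = {
    "jan": "01", "feb": "02", "mar": "03", "apr": "04", "may": "05",
    "jun": "06", "jul": "07", "aug": "08", "sep": "09", "oct": "10",
    "nov": "11", "dec": "12",
}


def _text(node: etree._Element | None) -> str:
    return "".join(node.itertext()).strip() if node is not None else ""


def _extract_fields(article: etree._Element) -> dict:
    citation = article.find("MedlineCitation")
    if citation is None:
        citation = article
    art = citation.find("Article")
    pmid = _text(citation.find("PMID"))
    title = _text(art.find("ArticleTitle")) if art is not None else ""
    abstract = ""
    if art is not None:
        parts = [_text(t) for t in art.findall("Abstract/AbstractText")]
        abstract = strip_subheadings(" ".join(p for p in parts if p))
    journal = _text(art.find("Journal/Title")) if art is not None else ""
    pub_date = ""
    if art is not None:
        date = art.find("Journal/JournalIssue/PubDate")
        if date is not None:
            year = _text(date.find("Year"))
            month = _text(date.find("Month")).lower()[:3]
            day = _text(date.find("Day"))
            if year:
                pub_date = year
                if month:
                    pub_date += "-" + _MONTHS.get(month, month if month.isdigit() else "")
                    pub_date = pub_date.rstrip("-")
                    if day:
                        pub_date += "-" + day.zfill(2)
            else:
                medline_date = _text(date.find("MedlineDate"))
                m = re.search(r"\b(1[89]\d{2}|20\d{2})\b", medline_date)
                pub_date = m.group(1) if m else ""
    article_types = [
        _text(t) for t in (art.findall("PublicationTypeList/PublicationType") if art is not None else [])
    ]
    article_types = [t for t in article_types if t]
    authors = []
    if art is not None:
        for a in art.findall("AuthorList/Author"):
            last, initials = _text(a.find("LastName")), _text(a.find("Initials"))
            collective = _text(a.find("CollectiveName"))
            name = f"{last} {initials}".strip() or collective
            if name:
                authors.append(name)
    return {
        "pmid": pmid,
        "title": title,
        "abstract": abstract,
        "pub_date": pub_date,
        "journal": journal,
        "article_types": article_types,
        "authors": authors,
    }


def sentence_split(
    record: AbstractRecord, splitter: SentenceSplitter | None = None
) -> list[Sentence]:
    """Split a cleaned abstract into offset-tracked sentences.

    Guarantees ``record.abstract_text[s.char_start:s.char_end] == s.text``
    for every returned sentence, in order and non-overlapping; an empty
    abstract yields an empty list.
    """
    splitter = splitter or RuleSentenceSplitter()
    spans = splitter.split(record.abstract_text)
    return [
        Sentence(
            record_pmid=record.pmid,
            index=i,
            text=record.abstract_text[start:end],
            char_start=start,
            char_end=end,
        )
        for i, (start, end) in enumerate(spans)
    ]


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

RECORD_COLUMNS = ("pmid", "title", "abstract_text", "pub_date", "journal",
                  "article_types", "authors")


def records_to_tsv(records: Iterable[AbstractRecord], path: str) -> None:
    """One row per record; list fields joined with '|'."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(RECORD_COLUMNS) + "\n")
        for r in records:
            row = [
                r.pmid,
                _flat(r.title),
                _flat(r.abstract_text),
                r.pub_date,
                _flat(r.journal),
                "|".join(r.article_types),
                "|".join(r.authors),
            ]
            fh.write("\t".join(row) + "\n")


def records_to_jsonl(records: Iterable[AbstractRecord], path: str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for r in records:
            fh.write(json.dumps(r.__dict__, ensure_ascii=False, sort_keys=True) + "\n")


def _flat(text: str) -> str:
    return text.replace("\t", " ").replace("\n", " ")
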