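"""Study-category assignment, the biomarker collocation query, and table
export/import.

Category rules operate on the MeSH tree positions of an abstract's disease
mentions plus its sentence annotations:

* C23.*                -> Signs & Symptoms
* C20.452.* or E04.*   -> Transplantation
* drug + allele + disease co-mentioned in one sentence AND (the disease sits
  in the configured ADR subtree, or the sentence carries "reactions" /
  "-induced" tokens, or the disease keyword itself contains "-induced")
                       -> Therapeutics/ADR
* any remaining C-branch hit -> Diseases (the residual class)
"""

from __future__ import annotations

import json
import logging
import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from hlalit.lexicons.diseases import DiseaseLexicon
from hlalit.text import tokenize
from hlalit.types import (
    AbstractRecord,
    MentionKind,
    PopulationTag,
    SentenceAnnotation,
    StudyCategory,
)

logger = logging.getLogger(__name__)

DEFAULT_ADR_TREE_PREFIXES = ("C25.723",)

#: Priority when exclusive single-category assignment is requested.
_EXCLUSIVE_PRIORITY = (
    StudyCategory.THERAPEUTICS_ADR,
    StudyCategory.TRANSPLANTATION,
    StudyCategory.SIGNS_SYMPTOMS,
    StudyCategory.DISEASES,
)


def _tree_hits(annotations: Sequence[SentenceAnnotation], lexicon: DiseaseLexicon):
    for ann in annotations:
        for m in ann.mentions_of(MentionKind.DISEASE):
            trees = lexicon.trees_for_mesh(m.canonical)
            if not trees:
                logger.info("disease mention %r (%s) has no tree number; ignored "
                            "for categorization", m.surface, m.canonical)
                continue
            yield ann, m, trees


def _sentence_has_adr_token(ann: SentenceAnnotation) -> bool:
    for t in tokenize(ann.sentence.text):
        low = t.lower
        if low == "reactions" or "-induced" in low:
            return True
    return False


def categorize_abstract(
    annotations: Sequence[SentenceAnnotation],
    lexicon: DiseaseLexicon,
    *,
    adr_tree_prefixes: Sequence[str] = DEFAULT_ADR_TREE_PREFIXES,
    exclusive: bool = False,
) -> set[StudyCategory]:
    """Category set for one abstract from its annotated sentences.

    Multi-category membership is the default; ``exclusive=True`` keeps only
    the highest-priority category (ADR > Transplantation > Signs & Symptoms
    > Diseases).
    """
    cats: set[StudyCategory] = set()
    for ann, m, trees in _tree_hits(annotations, lexicon):
        for t in trees:
            if t == "C23" or t.startswith("C23."):
                cats.add(StudyCategory.SIGNS_SYMPTOMS)
            elif t == "C20.452" or t.startswith("C20.452.") or t == "E04" or t.startswith("E04."):
                cats.add(StudyCategory.TRANSPLANTATION)
            elif t.startswith("C"):
                cats.add(StudyCategory.DISEASES)

    for ann in annotations:
        if not (
            ann.mentions_of(MentionKind.DRUG)
            and ann.mentions_of(MentionKind.ALLELE)
            and ann.mentions_of(MentionKind.DISEASE)
        ):
            continue
        sentence_token_hit = _sentence_has_adr_token(ann)
        for m in ann.mentions_of(MentionKind.DISEASE):
            trees = lexicon.trees_for_mesh(m.canonical)
            in_adr_branch = any(
                t == p or t.startswith(p + ".") for t in trees for p in adr_tree_prefixes
            )
            if in_adr_branch or sentence_token_hit or "-induced" in m.surface.lower():
                cats.add(StudyCategory.THERAPEUTICS_ADR)
                break

    if exclusive and cats:
        for c in _EXCLUSIVE_PRIORITY:
            if c in cats:
                return {c}
    return cats


def biomarker_query(
    sentences: Iterable[str], anchor: str = "marker", n: int = 2
) -> list[tuple[str, int]]:
    """Rank n-grams ending in the anchor token by corpus frequency.

    The default finds the words most frequently preceding "marker"
    ("genetic marker", "risk marker", ...).  Returns [] when the anchor is
    absent.
    """
    anchor = anchor.lower()
    counts: Counter[str] = Counter()
    for text in sentences:
        toks = [t.lower for t in tokenize(text)]
        for i in range(n - 1, len(toks)):
            if toks[i] == anchor:
                counts[" ".join(toks[i - n + 1 : i + 1])] += 1
    ranked = sorted(counts.items(), key=lambda gc: (-gc[1], gc[0]))
    return ranked


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

MENTION_COLUMNS = ["pmid", "sentence_index", "kind", "surface", "canonical",
                   "char_start", "char_end", "search_variant", "ambiguous", "candidates"]
LABEL_COLUMNS = ["pmid", "sentence_index", "stage1", "verb", "verb_class", "final_label"]
CATEGORY_COLUMNS = ["pmid", "category"]
POPULATION_COLUMNS = ["pmid", "surface", "normalized", "bin"]
SNP_COLUMNS = ["pmid", "sentence_index", "rsid"]


@dataclass
class ExportBundle:
    """Everything one pipeline run writes: per-table DataFrames + summary."""

    abstracts: pd.DataFrame
    mentions: pd.DataFrame
    sentence_labels: pd.DataFrame
    categories: pd.DataFrame
    populations: pd.DataFrame
    snps: pd.DataFrame
    summary: dict = field(default_factory=dict)

    FILES = {
        "abstracts": "abstracts.tsv",
        "mentions": "mentions.tsv",
        "sentence_labels": "sentence_labels.tsv",
        "categories": "categories.tsv",
        "populations": "populations.tsv",
        "snps": "snps.tsv",
    }


def build_export_bundle(
    records: Sequence[AbstractRecord],
    annotations_by_pmid: dict[str, list[SentenceAnnotation]],
    categories_by_pmid: dict[str, set[StudyCategory]],
    populations_by_pmid: dict[str, list[PopulationTag]],
) -> ExportBundle:
    """Assemble deterministic, sorted export tables from a pipeline run."""
    abstracts = pd.DataFrame(
        [
            {
                "pmid": r.pmid,
                "title": r.title,
                "abstract_text": r.abstract_text,
                "pub_date": r.pub_date,
                "journal": r.journal,
                "article_types": "|".join(r.article_types),
                "authors": "|".join(r.authors),
            }
            for r in records
        ],
        columns=["pmid", "title", "abstract_text", "pub_date", "journal",
                 "article_types", "authors"],
    )

    mention_rows, label_rows, snp_rows = [], [], []
    for pmid in sorted(annotations_by_pmid):
        for ann in annotations_by_pmid[pmid]:
            for m in sorted(ann.mentions, key=lambda m: (m.char_start, m.char_end, m.kind.value)):
                if m.kind == MentionKind.SNP:
                    snp_rows.append({"pmid": pmid, "sentence_index": ann.sentence.index,
                                     "rsid": m.canonical})
                    continue
                mention_rows.append({
                    "pmid": pmid,
                    "sentence_index": ann.sentence.index,
                    "kind": m.kind.value,
                    "surface": m.surface,
                    "canonical": m.canonical,
                    "char_start": m.char_start,
                    "char_end": m.char_end,
                    "search_variant": m.search_variant,
                    "ambiguous": m.ambiguous,
                    "candidates": "|".join(m.candidates),
                })
            label_rows.append({
                "pmid": pmid,
                "sentence_index": ann.sentence.index,
                "stage1": ann.stage1.value if ann.stage1 else "",
                "verb": ann.root_verb,
                "verb_class": ann.verb_class.value,
                "final_label": ann.final_label.value if ann.final_label else "",
            })

    cat_rows = [
        {"pmid": pmid, "category": c.value}
        for pmid in sorted(categories_by_pmid)
        for c in sorted(categories_by_pmid[pmid], key=lambda c: c.value)
    ]
    pop_rows = [
        {"pmid": pmid, "surface": t.surface, "normalized": t.normalized, "bin": t.bin}
        for pmid in sorted(populations_by_pmid)
        for t in sorted(populations_by_pmid[pmid], key=lambda t: (t.normalized, t.bin))
    ]

    bundle = ExportBundle(
        abstracts=abstracts.sort_values("pmid", kind="mergesort").reset_index(drop=True),
        mentions=pd.DataFrame(mention_rows, columns=MENTION_COLUMNS),
        sentence_labels=pd.DataFrame(label_rows, columns=LABEL_COLUMNS),
        categories=pd.DataFrame(cat_rows, columns=CATEGORY_COLUMNS),
        populations=pd.DataFrame(pop_rows, columns=POPULATION_COLUMNS),
        snps=pd.DataFrame(snp_rows, columns=SNP_COLUMNS),
    )
    bundle.summary = {
        "n_abstracts": int(len(abstracts)),
        "n_sentences_labeled": int(len(bundle.sentence_labels)),
        "n_mentions": int(len(bundle.mentions)),
        "n_snp_mentions": int(len(bundle.snps)),
        "label_counts": dict(
            sorted(Counter(bundle.sentence_labels["final_label"]).items())
        ) if len(bundle.sentence_labels) else {},
        "category_counts": dict(
            sorted(Counter(bundle.categories["category"]).items())
        ) if len(bundle.categories) else {},
    }
    return bundle


def export_tables(bundle: ExportBundle, outdir: str) -> dict[str, str]:
    """Write all tables as UTF-8 TSV plus ``summary.json``; deterministic
    column order and row sort so identical runs are byte-identical."""
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}
    for attr, fname in ExportBundle.FILES.items():
        path = os.path.join(outdir, fname)
        getattr(bundle, attr).to_csv(path, sep="\t", index=False, lineterminator="\n")
        paths[attr] = path
    spath = os.path.join(outdir, "summary.json")
    with open(spath, "w", encoding="utf-8") as fh:
        json.dump(bundle.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["summary"] = spath
    return paths


def import_tables(outdir: str) -> ExportBundle:
    """Re-read an export directory; inverse of :func:`export_tables`."""
    def read(fname: str, str_cols: Iterable[str]) -> pd.DataFrame:
        df = pd.read_csv(os.path.join(outdir, fname), sep="\t",
                         dtype={c: str for c in str_cols}, keep_default_na=False)
        return df

    bundle = ExportBundle(
        abstracts=read("abstracts.tsv", ["pmid", "pub_date", "article_types", "authors",
                                         "title", "abstract_text", "journal"]),
        mentions=read("mentions.tsv", ["pmid", "kind", "surface", "canonical",
                                       "search_variant", "candidates"]),
        sentence_labels=read("sentence_labels.tsv", ["pmid", "stage1", "verb",
                                                     "verb_class", "final_label"]),
        categories=read("categories.tsv", ["pmid", "category"]),
        populations=read("populations.tsv", ["pmid", "surface", "normalized", "bin"]),
        snps=read("snps.tsv", ["pmid", "rsid"]),
    )
    with open(os.path.join(outdir, "summary.json"), encoding="utf-8") as fh:
        bundle.summary = json.load(fh)
    return bundle
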