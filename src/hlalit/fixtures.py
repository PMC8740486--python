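"""Seeded miniature corpora and lexicon source files with planted truth.

``generate_corpus`` emits valid PubMed-dialect XML whose every entity
mention, sentence label, rsID, population and study category is known by
construction (templates are sentence skeletons slot-filled from pools the
mini-lexicons cover); ``generate_lexicon_sources`` writes the matching
allele list, allele-name history, MRCONSO-dialect concept file, MeSH tree
table and drug TSV.  Truth tables are serialized beside the corpus so any
pipeline stage can be scored offline.

Truth categories are re-derived here directly from the planted slots and the
literal tree table below — an independent application of the category rules,
not a call into :mod:`hlalit.categorize`.
"""

from __future__ import annotations

import os
import random
from dataclasses import dataclass, field
from typing import Callable

import pandas as pd
import yaml
from lxml import etree
from pydantic import BaseModel, Field, model_validator

# ---------------------------------------------------------------------------
# Planted entity pools (kept in lock-step with generate_lexicon_sources)
# ---------------------------------------------------------------------------

#: canonical -> surface spellings that may be planted in text
ALLELES: dict[str, tuple[str, ...]] = {
    "HLA-B*13:01": ("HLA-B*13:01", "HLA-B*1301", "B*1301", "B(*)1301", "B1301"),
    "HLA-B*15:02": ("HLA-B*15:02", "B*1502"),
    "HLA-A*31:01": ("HLA-A*31:01", "A*3101"),
    "HLA-B*57:01": ("HLA-B*57:01", "B*5701"),
    "HLA-DRB1*15": ("HLA-DRB1*15", "DRB1*15"),
    "HLA-B*27": ("HLA-B27", "B27"),
    "HLA-DQB1*06:02": ("HLA-DQB1*06:02", "DQB1*0602"),
    "HLA-C*06:02": ("Cw*0602",),  # retired spelling mapped via history
}

BROAD_ANTIGEN = ("HLA-A9", ("HLA-A*23", "HLA-A*24"))

#: mesh_id -> tree numbers (mini MeSH; mirrors the generated tree table)
TREES: dict[str, tuple[str, ...]] = {
    "D013167": ("C05.116.900",),
    "D009103": ("C10.114.375", "C20.111.258"),
    "D003922": ("C18.452.394", "C20.111.327"),
    "D013262": ("C25.723.260",),
    "D056486": ("C25.723.320",),
    "D006086": ("C20.452",),
    "D007668": ("E04.550.500",),
    "D005334": ("C23.888.119",),
    "D009369": ("C04",),
    "D014397": ("C01.252.410",),
    "D006111": ("C19.874.397", "C20.111.545"),
}

#: general disease pool: (planted surface, mesh_id)
GEN_DISEASES: tuple[tuple[str, str], ...] = (
    ("ankylosing spondylitis", "D013167"),
    ("multiple sclerosis", "D009103"),
    ("type 1 diabetes", "D003922"),
    ("Graves' disease", "D006111"),
    ("Graves disease", "D006111"),
    ("pulmonary tuberculosis", "D014397"),
    ("cancer", "D009369"),
    ("malignancy", "D009369"),
)

ADR_DISEASES: tuple[tuple[str, str], ...] = (
    ("Stevens-Johnson syndrome", "D013262"),
    ("Stevens Johnson syndrome", "D013262"),
)
DILI = ("Drug-induced liver injury", "D056486")
TX_DISEASES: tuple[tuple[str, str], ...] = (
    ("graft-versus-host disease", "D006086"),
    ("kidney transplantation", "D007668"),
)
SIGNS_DISEASE = ("fever", "D005334")

SIDER_DRUGS = ("carbamazepine", "abacavir", "insulin", "dapsone", "allopurinol")
EXTRA_DRUGS = {"AFND": ["methimazole", "carbimazole"], "PharmGKB": ["azathioprine", "abacavir"]}
ADR_TEMPLATE_DRUGS = ("carbamazepine", "abacavir", "dapsone", "allopurinol", "methimazole")

#: demonym -> (normalized, bin)
POPULATIONS: dict[str, tuple[str, str]] = {
    "Japanese": ("Japan", "country"),
    "Chinese": ("China", "country"),
    "Indian": ("India", "country"),
    "Han": ("Han", "ethnic_group"),
    "European": ("European", "ethnic_group"),
}


# ---------------------------------------------------------------------------
# Sentence construction
# ---------------------------------------------------------------------------

@dataclass
class PlannedMention:
    kind: str
    surface: str
    canonical: str
    char_start: int
    char_end: int
    ambiguous: bool = False
    candidates: tuple[str, ...] = ()


@dataclass
class PlannedSentence:
    template: str
    text: str = ""
    mentions: list[PlannedMention] = field(default_factory=list)
    rsids: list[str] = field(default_factory=list)
    stage1: str = ""
    final_label: str = ""
    populations: list[tuple[str, str]] = field(default_factory=list)
    has_drug_slot: bool = False  # a drug is present as a *mention* in truth


class _Builder:
    def __init__(self) -> None:
        self.parts: list[str] = []
        self.pos = 0
        self.mentions: list[PlannedMention] = []

    def text(self, s: str) -> "_Builder":
        self.parts.append(s)
        self.pos += len(s)
        return self

    def entity(self, kind: str, surface: str, canonical: str,
               ambiguous: bool = False, candidates: tuple[str, ...] = ()) -> "_Builder":
        self.mentions.append(
            PlannedMention(kind, surface, canonical, self.pos, self.pos + len(surface),
                           ambiguous, candidates)
        )
        return self.text(surface)

    def build(self) -> tuple[str, list[PlannedMention]]:
        return "".join(self.parts), self.mentions


def _pick_allele(rng: random.Random) -> tuple[str, str]:
    canonical = rng.choice(sorted(ALLELES))
    return rng.choice(ALLELES[canonical]), canonical


def _pick(rng: random.Random, pool: tuple) -> tuple:
    return pool[rng.randrange(len(pool))]


# Each template returns a PlannedSentence with exact truth attached.

def _t_positive(rng: random.Random) -> PlannedSentence:
    surf, canon = _pick_allele(rng)
    dsurf, dmesh = _pick(rng, GEN_DISEASES)
    pop = rng.choice(sorted(POPULATIONS))
    b = _Builder()
    b.entity("allele", surf, canon).text(" was significantly associated with ")
    b.entity("disease", dsurf, dmesh).text(f" in {pop} patients.")
    text, mentions = b.build()
    return PlannedSentence("positive", text, mentions, [], "positive", "Positive",
                           [POPULATIONS[pop]])


def _t_negative(rng: random.Random) -> PlannedSentence:
    surf, canon = _pick_allele(rng)
    dsurf, dmesh = _pick(rng, GEN_DISEASES)
    b = _Builder()
    b.entity("allele", surf, canon).text(" significantly protected against ")
    b.entity("disease", dsurf, dmesh).text(".")
    text, mentions = b.build()
    return PlannedSentence("negative", text, mentions, [], "negative", "Negative")


def _t_negation(rng: random.Random) -> PlannedSentence:
    surf, canon = _pick_allele(rng)
    dsurf, dmesh = _pick(rng, GEN_DISEASES)
    b = _Builder()
    b.text("No ").entity("allele", surf, canon).text(" carriers were identified among ")
    b.entity("disease", dsurf, dmesh).text(" patients.")
    text, mentions = b.build()
    return PlannedSentence("negation", text, mentions, [], "negation", "Ambiguous")


def _t_ambiguous(rng: random.Random) -> PlannedSentence:
    surf, canon = _pick_allele(rng)
    dsurf, dmesh = _pick(rng, GEN_DISEASES)
    b = _Builder()
    b.entity("allele", surf, canon).text(" was not significantly associated with ")
    b.entity("disease", dsurf, dmesh).text(".")
    text, mentions = b.build()
    return PlannedSentence("ambiguous", text, mentions, [], "ambiguous", "Ambiguous")


def _t_investigatory(rng: random.Random) -> PlannedSentence:
    surf, canon = _pick_allele(rng)
    dsurf, dmesh = _pick(rng, GEN_DISEASES)
    b = _Builder()
    b.text("To investigate the association of ").entity("allele", surf, canon)
    b.text(" with ").entity("disease", dsurf, dmesh).text(", we genotyped the cohort.")
    text, mentions = b.build()
    return PlannedSentence("investigatory", text, mentions, [], "others", "Investigatory")


def _t_complex(rng: random.Random) -> PlannedSentence:
    surf, canon = _pick_allele(rng)
    d1, d2 = rng.sample(list(GEN_DISEASES), 2)
    while d2[1] == d1[1]:
        d2 = _pick(rng, GEN_DISEASES)
    b = _Builder()
    b.entity("allele", surf, canon).text(" was significantly associated with ")
    b.entity("disease", d1[0], d1[1]).text(" but protected against ")
    b.entity("disease", d2[0], d2[1]).text(".")
    text, mentions = b.build()
    return PlannedSentence("complex", text, mentions, [], "complex", "Complex")


def _t_others(rng: random.Random) -> PlannedSentence:
    surf, canon = _pick_allele(rng)
    dsurf, dmesh = _pick(rng, GEN_DISEASES)
    b = _Builder()
    b.entity("allele", surf, canon).text(" was genotyped in patients with ")
    b.entity("disease", dsurf, dmesh).text(".")
    text, mentions = b.build()
    return PlannedSentence("others", text, mentions, [], "others", "Others")


def _t_guard(rng: random.Random) -> PlannedSentence:
    surf, canon = _pick_allele(rng)
    dsurf, dmesh = _pick(rng, GEN_DISEASES)
    b = _Builder()
    b.entity("allele", surf, canon).text(" negative patients developed ")
    b.entity("disease", dsurf, dmesh).text(".")
    text, mentions = b.build()
    return PlannedSentence("guard", text, mentions, [], "others", "Others")


def _t_adr(rng: random.Random) -> PlannedSentence:
    surf, canon = _pick_allele(rng)
    drug = rng.choice(ADR_TEMPLATE_DRUGS)
    pop = rng.choice(sorted(POPULATIONS))
    b = _Builder()
    pops: list[tuple[str, str]] = []
    if rng.random() < 0.5:
        dsurf, dmesh = _pick(rng, ADR_DISEASES)
        b.entity("drug", drug.capitalize(), drug).text("-induced ")
        b.entity("disease", dsurf, dmesh).text(" was significantly associated with ")
        b.entity("allele", surf, canon).text(f" in {pop} patients.")
        pops.append(POPULATIONS[pop])
    else:
        dsurf, dmesh = DILI
        b.entity("disease", dsurf, dmesh).text(" was significantly associated with ")
        b.entity("allele", surf, canon).text(" in patients receiving ")
        b.entity("drug", drug, drug).text(".")
    text, mentions = b.build()
    ps = PlannedSentence("adr", text, mentions, [], "positive", "Positive", pops)
    ps.has_drug_slot = True
    return ps


def _t_transplant(rng: random.Random) -> PlannedSentence:
    surf, canon = _pick_allele(rng)
    dsurf, dmesh = _pick(rng, TX_DISEASES)
    b = _Builder()
    b.entity("allele", surf, canon).text(" was strongly associated with ")
    b.entity("disease", dsurf, dmesh).text(".")
    text, mentions = b.build()
    return PlannedSentence("transplant", text, mentions, [], "positive", "Positive")


def _t_signs(rng: random.Random) -> PlannedSentence:
    surf, canon = _pick_allele(rng)
    dsurf, dmesh = SIGNS_DISEASE
    b = _Builder()
    b.entity("allele", surf, canon).text(" was significantly associated with ")
    b.entity("disease", dsurf, dmesh).text(".")
    text, mentions = b.build()
    return PlannedSentence("signs", text, mentions, [], "positive", "Positive")


def _t_snp(rng: random.Random) -> PlannedSentence:
    surf, canon = _pick_allele(rng)
    dsurf, dmesh = _pick(rng, GEN_DISEASES)
    rsid = f"rs{rng.randint(100, 99999999)}"
    b = _Builder()
    b.entity("allele", surf, canon).text(f" and {rsid} were significantly associated with ")
    b.entity("disease", dsurf, dmesh).text(".")
    text, mentions = b.build()
    return PlannedSentence("snp", text, mentions, [rsid], "positive", "Positive")


def _t_drugfp(rng: random.Random) -> PlannedSentence:
    surf, canon = _pick_allele(rng)
    b = _Builder()
    b.entity("allele", surf, canon).text(" was significantly associated with ")
    b.entity("disease", "insulin dependent diabetes mellitus", "D003922").text(".")
    text, mentions = b.build()
    return PlannedSentence("drugfp", text, mentions, [], "positive", "Positive")


def _t_broad(rng: random.Random) -> PlannedSentence:
    group, candidates = BROAD_ANTIGEN
    dsurf, dmesh = _pick(rng, GEN_DISEASES)
    b = _Builder()
    b.entity("allele", group, group, ambiguous=True, candidates=candidates)
    b.text(" was significantly associated with ")
    b.entity("disease", dsurf, dmesh).text(".")
    text, mentions = b.build()
    return PlannedSentence("broad", text, mentions, [], "positive", "Positive")


TEMPLATES: dict[str, Callable[[random.Random], PlannedSentence]] = {
    "positive": _t_positive,
    "negative": _t_negative,
    "negation": _t_negation,
    "ambiguous": _t_ambiguous,
    "investigatory": _t_investigatory,
    "complex": _t_complex,
    "others": _t_others,
    "guard": _t_guard,
    "adr": _t_adr,
    "transplant": _t_transplant,
    "signs": _t_signs,
    "snp": _t_snp,
    "drugfp": _t_drugfp,
    "broad": _t_broad,
}

FILLER = "The cohort comprised several hundred unrelated individuals."


def default_class_counts(n_abstracts: int) -> dict[str, int]:
    """~1.65 planted sentences per abstract at the default mix."""
    weights = {
        "positive": 18, "negative": 11, "negation": 8, "ambiguous": 8,
        "investigatory": 8, "complex": 6, "others": 8, "guard": 6,
        "adr": 8, "transplant": 6, "signs": 4, "snp": 6, "drugfp": 3, "broad": 2,
    }
    total = sum(weights.values())
    return {k: max(1, round(v * n_abstracts * 1.65 / total)) for k, v in weights.items()}


class FixtureSpec(BaseModel):
    """Study conditions of a synthetic corpus run."""

    n_abstracts: int = 200
    seed: int = 0
    class_counts: dict[str, int] = Field(default_factory=dict)
    filler_probability: float = 0.35
    n_incomplete: int = 0   # extra records lacking an abstract (parser food)

    @model_validator(mode="after")
    def _check(self) -> "FixtureSpec":
        if not self.class_counts:
            self.class_counts = default_class_counts(self.n_abstracts)
        unknown = set(self.class_counts) - set(TEMPLATES)
        if unknown:
            raise ValueError(f"unknown template classes: {sorted(unknown)}")
        if sum(self.class_counts.values()) < self.n_abstracts:
            raise ValueError("need at least one planted sentence per abstract")
        return self


@dataclass
class CorpusFixture:
    """In-memory corpus + truth; files are written next to ``xml_path``."""

    spec: FixtureSpec
    xml_path: str
    abstracts: list[dict]                 # pmid, title, text, sentences
    truth_mentions: pd.DataFrame
    truth_sentences: pd.DataFrame
    truth_categories: pd.DataFrame
    truth_populations: pd.DataFrame
    truth_snps: pd.DataFrame


def _truth_categories_for(sentences: list[PlannedSentence]) -> set[str]:
    """Independent application of the category rules to planted slots."""
    cats: set[str] = set()
    for ps in sentences:
        diseases = [m for m in ps.mentions if m.kind == "disease"]
        for m in diseases:
            for t in TREES.get(m.canonical, ()):
                if t.startswith("C23"):
                    cats.add("SignsSymptoms")
                elif t.startswith("C20.452") or t.startswith("E04"):
                    cats.add("Transplantation")
                elif t.startswith("C"):
                    cats.add("Diseases")
        has_drug = any(m.kind == "drug" for m in ps.mentions)
        has_allele = any(m.kind == "allele" for m in ps.mentions)
        if has_drug and has_allele and diseases:
            token_hit = "reactions" in ps.text.lower() or "-induced" in ps.text.lower()
            for m in diseases:
                in_branch = any(t.startswith("C25.723") for t in TREES.get(m.canonical, ()))
                if in_branch or token_hit or "-induced" in m.surface.lower():
                    cats.add("TherapeuticsADR")
                    break
    return cats


def generate_corpus(spec: FixtureSpec, outdir: str) -> CorpusFixture:
    """Write ``corpus.xml`` plus truth tables; fully determined by the seed."""
    os.makedirs(outdir, exist_ok=True)
    rng = random.Random(spec.seed)

    slots: list[str] = []
    for cls in sorted(spec.class_counts):
        slots += [cls] * spec.class_counts[cls]
    rng.shuffle(slots)

    # deal sentences to abstracts: one guaranteed each, remainder round-robin
    per_abstract: list[list[str]] = [[] for _ in range(spec.n_abstracts)]
    for i, cls in enumerate(slots):
        per_abstract[i % spec.n_abstracts].append(cls)

    abstracts: list[dict] = []
    mention_rows, sent_rows, cat_rows, pop_rows, snp_rows = [], [], [], [], []
    for a_idx, classes in enumerate(per_abstract):
        pmid = str(10_000_001 + a_idx)
        planned = [TEMPLATES[cls](rng) for cls in classes]
        sentences: list[PlannedSentence | None] = list(planned)
        if rng.random() < spec.filler_probability:
            sentences.insert(rng.randrange(len(sentences) + 1), None)
        texts = [FILLER if ps is None else ps.text for ps in sentences]
        abstract_text = " ".join(texts)
        title = f"An immunogenetic cohort analysis (report {a_idx + 1})."
        year = rng.randint(1985, 2021)

        pops: set[tuple[str, str]] = set()
        for s_idx, ps in enumerate(sentences):
            if ps is None:
                continue
            for m in ps.mentions:
                mention_rows.append({
                    "pmid": pmid, "sentence_index": s_idx, "kind": m.kind,
                    "surface": m.surface, "canonical": m.canonical,
                    "char_start": m.char_start, "char_end": m.char_end,
                    "ambiguous": m.ambiguous, "candidates": "|".join(m.candidates),
                })
            for rsid in ps.rsids:
                snp_rows.append({"pmid": pmid, "sentence_index": s_idx, "rsid": rsid})
            sent_rows.append({
                "pmid": pmid, "sentence_index": s_idx, "template": ps.template,
                "stage1": ps.stage1, "final_label": ps.final_label,
            })
            pops.update(ps.populations)
        for norm, b in sorted(pops):
            pop_rows.append({"pmid": pmid, "normalized": norm, "bin": b})
        for cat in sorted(_truth_categories_for(planned)):
            cat_rows.append({"pmid": pmid, "category": cat})
        abstracts.append({
            "pmid": pmid, "title": title, "abstract": abstract_text,
            "year": year, "journal": "Journal of Synthetic Immunogenetics",
            "article_type": "Journal Article",
            "authors": [("Doe", "J"), ("Roe", "R")],
            "complete": True,
        })

    for k in range(spec.n_incomplete):
        abstracts.append({
            "pmid": str(20_000_001 + k),
            "title": f"A record without an abstract ({k + 1}).",
            "abstract": "", "year": 2000,
            "journal": "Journal of Synthetic Immunogenetics",
            "article_type": "Journal Article", "authors": [("Doe", "J")],
            "complete": False,
        })

    xml_path = os.path.join(outdir, "corpus.xml")
    _write_xml(abstracts, xml_path)

    fixture = CorpusFixture(
        spec=spec,
        xml_path=xml_path,
        abstracts=abstracts,
        truth_mentions=pd.DataFrame(
            mention_rows, columns=["pmid", "sentence_index", "kind", "surface",
                                   "canonical", "char_start", "char_end",
                                   "ambiguous", "candidates"]),
        truth_sentences=pd.DataFrame(
            sent_rows, columns=["pmid", "sentence_index", "template", "stage1",
                                "final_label"]),
        truth_categories=pd.DataFrame(cat_rows, columns=["pmid", "category"]),
        truth_populations=pd.DataFrame(pop_rows, columns=["pmid", "normalized", "bin"]),
        truth_snps=pd.DataFrame(snp_rows, columns=["pmid", "sentence_index", "rsid"]),
    )
    for name in ("mentions", "sentences", "categories", "populations", "snps"):
        getattr(fixture, f"truth_{name}").to_csv(
            os.path.join(outdir, f"truth_{name}.tsv"), sep="\t", index=False,
            lineterminator="\n",
        )
    return fixture


def _write_xml(abstracts: list[dict], path: str) -> None:
    root = etree.Element("PubmedArticleSet")
    for a in abstracts:
        art = etree.SubElement(root, "PubmedArticle")
        cit = etree.SubElement(art, "MedlineCitation")
        etree.SubElement(cit, "PMID").text = a["pmid"]
        article = etree.SubElement(cit, "Article")
        journal = etree.SubElement(article, "Journal")
        etree.SubElement(journal, "Title").text = a["journal"]
        issue = etree.SubElement(journal, "JournalIssue")
        pubdate = etree.SubElement(issue, "PubDate")
        etree.SubElement(pubdate, "Year").text = str(a["year"])
        etree.SubElement(article, "ArticleTitle").text = a["title"]
        if a["abstract"]:
            abstract = etree.SubElement(article, "Abstract")
            etree.SubElement(abstract, "AbstractText").text = a["abstract"]
        authors = etree.SubElement(article, "AuthorList")
        for last, initials in a["authors"]:
            author = etree.SubElement(authors, "Author")
            etree.SubElement(author, "LastName").text = last
            etree.SubElement(author, "Initials").text = initials
        ptl = etree.SubElement(article, "PublicationTypeList")
        etree.SubElement(ptl, "PublicationType").text = a["article_type"]
    etree.ElementTree(root).write(
        path, encoding="utf-8", xml_declaration=True, pretty_print=True
    )


# ---------------------------------------------------------------------------
# Lexicon source files
# ---------------------------------------------------------------------------

ALLELE_LIST_ROWS = [
    ("HLA00001", "A*01:01"), ("HLA00002", "A*03:01"), ("HLA00003", "A*23:01"),
    ("HLA00004", "A*24:02"), ("HLA00005", "A*25:01"), ("HLA00006", "A*26:01"),
    ("HLA00007", "A*31:01:02"), ("HLA00008", "B*07:02"), ("HLA00009", "B*08:01"),
    ("HLA00010", "B*13:01:01"), ("HLA00011", "B*14:01"), ("HLA00012", "B*14:02"),
    ("HLA00013", "B*15:02:01"), ("HLA00014", "B*27:05"), ("HLA00015", "B*57:01:01"),
    ("HLA00016", "C*06:02:01"), ("HLA00017", "DQB1*06:02:01"),
    ("HLA00018", "DRB1*03:01"), ("HLA00019", "DRB1*15:01"), ("HLA00020", "DRB1*16:01"),
]

HISTORY_ROWS = [
    ("Cw*0602", "C*06:02"),
    ("B*2705", "B*27:05"),
    ("A*9901", ""),  # deleted allele, no successor: excluded from matching
]

MRCONSO_ROWS = [  # (surface, tty, mesh_id)
    ("ankylosing spondylitis", "ET", "D013167"),
    ("Spondylitis, Ankylosing", "PM", "D013167"),
    ("multiple sclerosis", "MH", "D009103"),
    ("type 1 diabetes", "ET", "D003922"),
    ("diabetes mellitus", "MH", "D003922"),
    ("insulin dependent diabetes mellitus", "ET", "D003922"),
    ("diabetes mellitus type 1", "DSV", "D003922"),
    ("Stevens-Johnson syndrome", "MH", "D013262"),
    ("Drug-induced liver injury", "MH", "D056486"),
    ("Graves' disease", "MH", "D006111"),
    ("Graves disease", "ET", "D006111"),
    ("graft-versus-host disease", "MH", "D006086"),
    ("kidney transplantation", "MH", "D007668"),
    ("fever", "MH", "D005334"),
    ("cancer", "ET", "D009369"),
    ("malignancy", "ET", "D009369"),
    ("tumor", "ET", "D009369"),
    ("neoplasms", "MH", "D009369"),
    ("neoplasm", "PEP", "D009369"),
    ("pulmonary tuberculosis", "ET", "D014397"),
    ("Tuberculosis, Pulmonary", "MH", "D014397"),
    ("abdominal inj", "DEV", "D000007"),  # truncated DEV string: must be excluded
]

MESH_TREE_ROWS = [  # (mesh_id, label, tree_number)
    ("D013167", "Spondylitis, Ankylosing", "C05.116.900"),
    ("D009103", "Multiple Sclerosis", "C10.114.375"),
    ("D009103", "Multiple Sclerosis", "C20.111.258"),
    ("D003922", "Diabetes Mellitus, Type 1", "C18.452.394"),
    ("D003922", "Diabetes Mellitus, Type 1", "C20.111.327"),
    ("D013262", "Stevens-Johnson Syndrome", "C25.723.260"),
    ("D056486", "Chemical and Drug Induced Liver Injury", "C25.723.320"),
    ("D006086", "Graft vs Host Disease", "C20.452"),
    ("D007668", "Kidney Transplantation", "E04.550.500"),
    ("D005334", "Fever", "C23.888.119"),
    ("D009369", "Neoplasms", "C04"),
    ("D014397", "Tuberculosis, Pulmonary", "C01.252.410"),
    ("D006111", "Graves Disease", "C19.874.397"),
    ("D006111", "Graves Disease", "C20.111.545"),
    # ancestors so level-zero/one rollups resolve
    ("D007239", "Infections", "C01"),
    ("D001424", "Bacterial Infections", "C01.252"),
    ("D009140", "Musculoskeletal Diseases", "C05"),
    ("D001847", "Bone Diseases", "C05.116"),
    ("D009422", "Nervous System Diseases", "C10"),
    ("D020274", "Autoimmune Diseases of the Nervous System", "C10.114"),
    ("D009750", "Nutritional and Metabolic Diseases", "C18"),
    ("D008659", "Metabolic Diseases", "C18.452"),
    ("D004700", "Endocrine System Diseases", "C19"),
    ("D013959", "Thyroid Diseases", "C19.874"),
    ("D007154", "Immune System Diseases", "C20"),
    ("D001327", "Autoimmune Diseases", "C20.111"),
    ("D013568", "Pathological Conditions, Signs and Symptoms", "C23"),
    ("D012816", "Signs and Symptoms", "C23.888"),
    ("D064419", "Chemically-Induced Disorders", "C25"),
    ("D011041", "Poisoning", "C25.723"),
    ("D013514", "Surgical Procedures, Operative", "E04"),
    ("D019737", "Transplantation", "E04.550"),
]

HLA_GROUPS = {
    "broad_antigens": {
        "HLA-A9": ["HLA-A*23", "HLA-A*24"],
        "HLA-A10": ["HLA-A*25", "HLA-A*26"],
    },
    "haplotypes": {"HLA-A1-B8-DR3": ["HLA-A*01", "HLA-B*08", "HLA-DRB1*03"]},
    "generic_keywords": ["HLA class I", "HLA class II", "HLA linked", "HLA associated"],
}


def generate_lexicon_sources(outdir: str) -> dict[str, str]:
    """Write miniature lexicon source files; returns name -> path.

    The files parse with the :mod:`hlalit.lexicons` readers and include at
    least one old-name history mapping, one DEV concept row and one
    broad-antigen config entry.
    """
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    paths["allele_list"] = os.path.join(outdir, "allelelist.csv")
    with open(paths["allele_list"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("AlleleID,Name\n")
        for aid, name in ALLELE_LIST_ROWS:
            fh.write(f"{aid},{name}\n")

    paths["allele_history"] = os.path.join(outdir, "allele_history.csv")
    with open(paths["allele_history"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("old,new\n")
        for old, new in HISTORY_ROWS:
            fh.write(f"{old},{new}\n")

    paths["mrconso"] = os.path.join(outdir, "mrconso.rrf")
    with open(paths["mrconso"], "w", encoding="utf-8", newline="\n") as fh:
        for i, (surface, tty, mesh_id) in enumerate(MRCONSO_ROWS):
            parts = [f"C{i:07d}", "ENG", "P", f"L{i:07d}", "PF", f"S{i:07d}",
                     "Y", f"A{i:07d}", "", "", "", "MSH", tty, mesh_id, surface, "0"]
            fh.write("|".join(parts) + "\n")

    paths["mesh_tree"] = os.path.join(outdir, "mesh_tree.tsv")
    with open(paths["mesh_tree"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("mesh_id\tlabel\ttree_number\n")
        for mesh_id, label, tree in MESH_TREE_ROWS:
            fh.write(f"{mesh_id}\t{label}\t{tree}\n")

    paths["sider_drugs"] = os.path.join(outdir, "drug_names.tsv")
    with open(paths["sider_drugs"], "w", encoding="utf-8", newline="\n") as fh:
        for i, name in enumerate(SIDER_DRUGS, start=1):
            fh.write(f"CID{i:09d}\t{name}\n")

    paths["hla_groups"] = os.path.join(outdir, "hla_groups.yaml")
    with open(paths["hla_groups"], "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(HLA_GROUPS, fh, sort_keys=True)

    return paths


def fixture_pipeline_config(outdir: str):
    """Convenience: generate lexicon sources and return a PipelineConfig."""
    from hlalit.config import LexiconPaths, PipelineConfig

    paths = generate_lexicon_sources(outdir)
    return PipelineConfig(
        lexicons=LexiconPaths(
            allele_list=paths["allele_list"],
            allele_history=paths["allele_history"],
            mrconso=paths["mrconso"],
            mesh_tree=paths["mesh_tree"],
            sider_drugs=paths["sider_drugs"],
            hla_groups=paths["hla_groups"],
            extra_drugs=EXTRA_DRUGS,
        )
    )
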