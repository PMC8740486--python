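"""Pipeline configuration (YAML-loadable) and resource bundle assembly."""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

import yaml
from pydantic import BaseModel, Field

from hlalit.lexicons.diseases import (
    DiseaseLexicon,
    build_disease_lexicon,
    read_mesh_tree,
    read_mrconso,
)
from hlalit.lexicons.drugs import DrugEntry, build_drug_lexicon, read_sider_names
from hlalit.lexicons.hla import (
    AlleleSurfaceMap,
    build_hla_lexicon,
    read_allele_history,
    read_allele_list,
)
from hlalit.semantics import LabelLexicon, VerbPolarity
from hlalit.taggers import PopulationTables


class LexiconPaths(BaseModel):
    """Input files the dictionaries are compiled from."""

    allele_list: str
    allele_history: Optional[str] = None
    mrconso: str
    mesh_tree: str
    sider_drugs: str
    hla_groups: Optional[str] = None          # broad antigens / haplotypes YAML
    label_lexicon: Optional[str] = None       # defaults to shipped table
    verb_polarity: Optional[str] = None       # defaults to shipped table
    extra_drugs: dict[str, list[str]] = Field(default_factory=dict)


class PipelineOptions(BaseModel):
    require_authors: bool = False
    title_sentences: bool = False       # titles screen but are not labeled
    guard_k: int = 2                    # carrier-status guard window (tokens)
    freq_cutoff: int = 10               # n-gram candidate frequency cut-off
    exclusive_categories: bool = False
    adr_tree_prefixes: list[str] = Field(default_factory=lambda: ["C25.723"])
    mrconso_columns: dict[str, int] = Field(default_factory=dict)


class PipelineConfig(BaseModel):
    lexicons: LexiconPaths
    options: PipelineOptions = Field(default_factory=PipelineOptions)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh))


@dataclass
class ResourceBundle:
    """Compiled dictionaries and rule tables for one pipeline run."""

    disease_lexicon: DiseaseLexicon
    allele_map: AlleleSurfaceMap
    drug_lexicon: list[DrugEntry]
    label_lexicon: LabelLexicon
    verb_polarity: VerbPolarity
    population_tables: PopulationTables


def load_population_tables() -> PopulationTables:
    """Shipped demonym->country and ethnic-group binning tables (editable
    stand-ins for the expert-curated originals)."""
    countries: dict[str, str] = {}
    text = resources.files("hlalit.data").joinpath("countries.tsv").read_text("utf-8")
    for line in text.splitlines():
        if not line.strip() or line.startswith("demonym\t"):
            continue
        demonym, _, country = line.partition("\t")
        countries[demonym.strip().lower()] = country.strip()
    groups = frozenset(
        l.strip().lower()
        for l in resources.files("hlalit.data").joinpath("ethnic_groups.txt")
        .read_text("utf-8").splitlines()
        if l.strip()
    )
    return PopulationTables(countries=countries, ethnic_groups=groups)


def build_resources(cfg: PipelineConfig) -> ResourceBundle:
    """Compile all dictionaries from the configured source files."""
    hierarchy = read_mesh_tree(cfg.lexicons.mesh_tree)
    rows = read_mrconso(cfg.lexicons.mrconso, **cfg.options.mrconso_columns)
    disease_lexicon = build_disease_lexicon(rows, hierarchy)

    names = [name for _, name in read_allele_list(cfg.lexicons.allele_list)]
    history = (
        read_allele_history(cfg.lexicons.allele_history)
        if cfg.lexicons.allele_history
        else []
    )
    groups: dict = {}
    if cfg.lexicons.hla_groups:
        with open(cfg.lexicons.hla_groups, encoding="utf-8") as fh:
            groups = yaml.safe_load(fh) or {}
    allele_map = build_hla_lexicon(
        names,
        history,
        broad_antigens=groups.get("broad_antigens"),
        haplotypes=groups.get("haplotypes"),
        generic_keywords=groups.get(
            "generic_keywords",
            ("HLA class I", "HLA class II", "HLA linked", "HLA associated"),
        ),
    )

    drug_lexicon = build_drug_lexicon(
        read_sider_names(cfg.lexicons.sider_drugs), cfg.lexicons.extra_drugs
    )
    label_lexicon = (
        LabelLexicon.from_tsv(cfg.lexicons.label_lexicon)
        if cfg.lexicons.label_lexicon
        else LabelLexicon.load_default()
    )
    verb_polarity = (
        VerbPolarity.from_tsv(cfg.lexicons.verb_polarity)
        if cfg.lexicons.verb_polarity
        else VerbPolarity.load_default()
    )
    return ResourceBundle(
        disease_lexicon=disease_lexicon,
        allele_map=allele_map,
        drug_lexicon=drug_lexicon,
        label_lexicon=label_lexicon,
        verb_polarity=verb_polarity,
        population_tables=load_population_tables(),
    )
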