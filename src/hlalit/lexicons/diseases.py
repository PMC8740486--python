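"""Disease keyword dictionary built from MeSH descriptors, with the tree
hierarchy used for level-zero/level-one rollups and study categorization.

Keywords come from an MRCONSO.RRF-dialect concept table restricted to the
MeSH descriptor types ET, MH, PEP, DSV and PM; the DEV type is excluded
because those strings are truncated ("abdominal inj").  Each retained
keyword also emits plural and lemmatized variants pointing at the same
descriptor, widening the literal search space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from hlalit.text import pluralize, singularize

logger = logging.getLogger(__name__)

INCLUDED_TTYS = {"ET", "MH", "PEP", "DSV", "PM"}
EXCLUDED_TTYS = {"DEV"}
VARIANT_TTYS = {"plural-variant", "lemma-variant"}


@dataclass(frozen=True)
class DiseaseEntry:
    """One searchable disease keyword pointing at a MeSH descriptor."""

    surface: str
    mesh_id: str
    descriptor_type: str
    tree_numbers: tuple[str, ...] = ()

    @property
    def unrooted(self) -> bool:
        return not self.tree_numbers


@dataclass
class MeshHierarchy:
    """MeSH descriptor nodes addressed by ID and by tree number.

    Tree numbers are dotted paths ("C20.111.258"); the level-zero ancestor
    of a tree number is the descriptor sitting at its first component
    ("C20"), level-one at the first two components ("C20.111").
    """

    labels: dict[str, str] = field(default_factory=dict)          # mesh_id -> label
    tree_numbers: dict[str, tuple[str, ...]] = field(default_factory=dict)
    tree_index: dict[str, str] = field(default_factory=dict)      # tree number -> mesh_id

    def add(self, mesh_id: str, label: str, trees: Iterable[str]) -> None:
        self.labels[mesh_id] = label
        existing = self.tree_numbers.get(mesh_id, ())
        new = tuple(dict.fromkeys(existing + tuple(trees)))
        self.tree_numbers[mesh_id] = new
        for t in new:
            self.tree_index[t] = mesh_id

    def ancestor(self, tree_number: str, level: int) -> str | None:
        """Descriptor ID at `level` of a tree number (0 = root category)."""
        parts = tree_number.split(".")
        if level >= len(parts):
            return self.tree_index.get(tree_number)
        return self.tree_index.get(".".join(parts[: level + 1]))

    def level_one_label(self, mesh_id: str) -> str:
        """Label of the level-one (falling back to level-zero) ancestor."""
        trees = self.tree_numbers.get(mesh_id, ())
        if not trees:
            return "unrooted"
        tree = sorted(trees)[0]
        anc = self.ancestor(tree, 1) or self.ancestor(tree, 0)
        if anc is None:
            return "unrooted"
        return self.labels.get(anc, anc)


@dataclass
class DiseaseLexicon:
    entries: list[DiseaseEntry]
    hierarchy: MeshHierarchy
    surface_index: dict[str, DiseaseEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.surface_index:
            # first writer wins so primary descriptor types take precedence
            for e in self.entries:
                self.surface_index.setdefault(e.surface.lower(), e)

    def lookup(self, surface: str) -> DiseaseEntry | None:
        return self.surface_index.get(surface.lower())

    def trees_for_mesh(self, mesh_id: str) -> tuple[str, ...]:
        return self.hierarchy.tree_numbers.get(mesh_id, ())


def read_mrconso(
    path: str,
    *,
    str_col: int = 14,
    tty_col: int = 12,
    id_col: int = 13,
    sab_col: int = 11,
    restrict_sab: str | None = "MSH",
) -> list[tuple[str, str, str]]:
    """Read (keyword, descriptor type, mesh id) from a pipe-delimited
    MRCONSO.RRF-dialect file.  Column indices are configurable; defaults
    follow the standard layout (SAB=11, TTY=12, CODE=13, STR=14).
    """
    rows: list[tuple[str, str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("|")
            if len(parts) <= max(str_col, tty_col, id_col):
                continue
            if restrict_sab and sab_col < len(parts) and parts[sab_col] != restrict_sab:
                continue
            rows.append((parts[str_col], parts[tty_col], parts[id_col]))
    return rows


def read_mesh_tree(path: str) -> MeshHierarchy:
    """TSV with columns ``mesh_id<TAB>label<TAB>tree_number`` (one row per
    tree number; repeated IDs accumulate)."""
    h = MeshHierarchy()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.lower().startswith("mesh_id"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                continue
            h.add(parts[0], parts[1], (parts[2],) if parts[2] else ())
    return h


def build_disease_lexicon(
    concept_rows: Iterable[tuple[str, str, str]],
    hierarchy: MeshHierarchy,
) -> DiseaseLexicon:
    """Compile the disease lexicon from concept rows and the tree table.

    Keeps ET/MH/PEP/DSV/PM rows, drops DEV, warns on unknown descriptor
    types.  For every retained keyword a plural and a lemmatized (singular)
    variant are added under the same MeSH ID when they differ from the
    original surface.
    """
    entries: list[DiseaseEntry] = []
    seen: set[tuple[str, str]] = set()

    def push(surface: str, tty: str, mesh_id: str) -> None:
        key = (surface.lower(), mesh_id)
        if key in seen or not surface.strip():
            return
        seen.add(key)
        entries.append(
            DiseaseEntry(surface.lower(), mesh_id, tty, hierarchy.tree_numbers.get(mesh_id, ()))
        )

    for surface, tty, mesh_id in concept_rows:
        if tty in EXCLUDED_TTYS:
            continue
        if tty not in INCLUDED_TTYS:
            logger.warning("skipping row with unknown descriptor type %r: %r", tty, surface)
            continue
        push(surface, tty, mesh_id)
        head, *rest = surface.rsplit(None, 1) if " " in surface else (surface,)
        last = rest[0] if rest else surface
        prefix = (head + " ") if rest else ""
        plural = prefix + pluralize(last)
        if plural.lower() != surface.lower():
            push(plural, "plural-variant", mesh_id)
        lemma = prefix + singularize(last)
        if lemma.lower() != surface.lower():
            push(lemma, "lemma-variant", mesh_id)

    for e in entries:
        if e.unrooted:
            logger.warning("disease entry %r (%s) has no tree number", e.surface, e.mesh_id)
    return DiseaseLexicon(entries=entries, hierarchy=hierarchy)


def normalize_disease(surface: str, lexicon: DiseaseLexicon) -> tuple[str, str]:
    """Map a matched keyword to (mesh_id, level-one ancestor label).

    Deterministic: "cancer", "tumour", "malignancy" and "neoplasm" all
    resolve to the malignancy descriptor D009369 when the lexicon routes
    them there.
    """
    entry = lexicon.lookup(surface)
    if entry is None:
        raise LookupError(f"unknown disease keyword: {surface!r}")
    return entry.mesh_id, lexicon.hierarchy.level_one_label(entry.mesh_id)
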