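"""HLA allele dictionary: nomenclature parsing, surface-variant generation
and normalization to current IMGT-style names.

The same allele appears in the literature under many spellings --
HLA-B*13:01, HLA-B*1301, B*1301, B(*)1301, B1301 -- plus retired names from
earlier nomenclature revisions (Cw*0602 for C*06:02).  The surface map
enumerates every recognized spelling and points each back to the canonical
colon-delimited name with the "HLA-" prefix.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

#: Allele categories.
CATEGORY_CURRENT = "current"
CATEGORY_OLD = "old-mapped"
CATEGORY_BROAD = "broad-antigen"
CATEGORY_HAPLOTYPE = "haplotype"
CATEGORY_GENERIC = "generic"

DEFAULT_GENERIC_KEYWORDS = (
    "HLA class I",
    "HLA class II",
    "HLA linked",
    "HLA associated",
)

_NAME_RE = re.compile(
    r"^(?:HLA-)?(?P<gene>[A-Z]+[0-9]*)\*(?P<fields>[0-9]+(?::[0-9]+)*)(?P<suffix>[NLSCAQ]?)$",
    re.IGNORECASE,
)
# serology-style name without '*': B27, DR2, Cw6
_SEROLOGY_RE = re.compile(r"^(?:HLA-)?(?P<gene>[A-Z]+w?[0-9]*?)(?P<field>[0-9]+)$", re.IGNORECASE)


class AlleleNameError(ValueError):
    """Name does not parse as an HLA allele."""


@dataclass(frozen=True)
class AlleleEntry:
    """One dictionary allele with its canonical name.

    For ``broad-antigen`` and ``haplotype`` entries ``candidates`` lists the
    two or more concrete canonical names the surface may stand for; for
    ``generic`` entries the canonical is the keyword itself and the name does
    not parse into gene + fields.
    """

    canonical: str
    gene: str
    fields: tuple[str, ...]
    category: str = CATEGORY_CURRENT
    candidates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.category == CATEGORY_BROAD and len(self.candidates) < 2:
            raise ValueError(f"broad-antigen entry {self.canonical} needs >=2 candidates")


def parse_allele_name(name: str) -> tuple[str, tuple[str, ...]]:
    """Split an allele name into (gene, numeric fields).

    >>> parse_allele_name("HLA-B*13:01")
    ('B', ('13', '01'))
    """
    m = _NAME_RE.match(name.strip())
    if not m:
        raise AlleleNameError(f"not a parseable allele name: {name!r}")
    return m.group("gene").upper(), tuple(m.group("fields").split(":"))


def canonical_name(gene: str, fields: Iterable[str]) -> str:
    return f"HLA-{gene.upper()}*{':'.join(fields)}"


def collapse_two_digit(canonical: str) -> str:
    """Collapse an allele name to its two-digit group (locus + first field).

    >>> collapse_two_digit("HLA-B*38:02:01")
    'HLA-B*38'

    Generic keywords ("HLA class I", ...) carry no fields and are not
    collapsible.
    """
    try:
        gene, fields = parse_allele_name(canonical)
    except AlleleNameError as exc:
        raise ValueError(f"not collapsible: {canonical!r}") from exc
    return canonical_name(gene, fields[:1])


def surface_variants(canonical: str) -> list[str]:
    """All lowercased written variants of a canonical allele name.

    Combinations of {with/without "HLA-" prefix} x {'*', '(*)', no star} x
    {with/without ':' separators}; e.g. HLA-B*13:01 yields hla-b*13:01,
    hla-b*1301, b*1301, b(*)1301, b1301, ...  Deduplicated, generation order.
    """
    gene, fields = parse_allele_name(canonical)
    g = gene.lower()
    out: list[str] = []
    for prefix in ("hla-", ""):
        for star in ("*", "(*)", ""):
            for sep in (":", ""):
                s = f"{prefix}{g}{star}{sep.join(fields)}"
                if s not in out:
                    out.append(s)
    return out


def _literal_variants(name: str) -> list[str]:
    """Variants of a name kept literal (old names that may not parse)."""
    base = name.strip().lower()
    forms = {base}
    if base.startswith("hla-"):
        forms.add(base[4:])
    else:
        forms.add("hla-" + base)
    for f in list(forms):
        if "*" in f:
            forms.add(f.replace("*", "(*)"))
            forms.add(f.replace("*", ""))
        if ":" in f:
            forms.add(f.replace(":", ""))
    # second pass so star/colon removals combine
    for f in list(forms):
        if "*" in f and ":" in f:
            forms.add(f.replace("*", "").replace(":", ""))
    return sorted(forms)


@dataclass
class AlleleSurfaceMap:
    """surface (lowercased post-preprocessing text) -> candidate entries."""

    surfaces: dict[str, list[AlleleEntry]] = field(default_factory=dict)

    def add(self, surface: str, entry: AlleleEntry) -> None:
        bucket = self.surfaces.setdefault(surface.lower(), [])
        if entry not in bucket:
            bucket.append(entry)

    def lookup(self, surface: str) -> list[AlleleEntry]:
        return self.surfaces.get(surface.lower(), [])

    def __contains__(self, surface: str) -> bool:
        return surface.lower() in self.surfaces

    def __len__(self) -> int:
        return len(self.surfaces)


@dataclass(frozen=True)
class AlleleNormalization:
    candidates: tuple[str, ...]
    ambiguous: bool
    display: str | None = None  # group name for broad-antigen/haplotype hits

    @property
    def canonical(self) -> str:
        return self.display or self.candidates[0]


def normalize_allele(surface: str, surface_map: AlleleSurfaceMap) -> AlleleNormalization:
    """Resolve a matched surface to canonical allele name(s).

    Unambiguous surfaces yield a singleton; broad-antigen surfaces (and rare
    cross-allele collisions) yield all candidates with ``ambiguous=True``.
    Idempotent: a canonical name normalizes to itself.
    """
    entries = surface_map.lookup(surface)
    if not entries:
        raise LookupError(f"unknown allele surface: {surface!r}")
    candidates: list[str] = []
    ambiguous = False
    display: str | None = None
    for e in entries:
        if e.category in (CATEGORY_BROAD, CATEGORY_HAPLOTYPE):
            ambiguous = True
            if display is None:
                display = e.canonical
            for c in e.candidates:
                if c not in candidates:
                    candidates.append(c)
        else:
            if e.canonical not in candidates:
                candidates.append(e.canonical)
    if len(candidates) > 1:
        ambiguous = True
    if len(entries) > 1:
        display = None  # cross-entry collision: no single group name
    return AlleleNormalization(tuple(candidates), ambiguous, display)


# ---------------------------------------------------------------------------
# Builders / readers
# ---------------------------------------------------------------------------

def read_allele_list(path: str) -> list[tuple[str, str]]:
    """IMGT Allelelist dialect: CSV with header ``AlleleID,Name``.

    Comment lines starting '#' are skipped; names lack the "HLA-" prefix.
    """
    rows: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        reader = csv.reader(line for line in fh if not line.startswith("#"))
        for row in reader:
            if not row or row[0].strip().lower() == "alleleid":
                continue
            if len(row) < 2:
                continue
            rows.append((row[0].strip(), row[1].strip()))
    return rows


def read_allele_history(path: str) -> list[tuple[str, str]]:
    """Old->current name table: CSV/TSV with columns ``old,new``.

    An empty ``new`` column marks a deleted allele with no successor.
    """
    rows: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in re.split(r"[,\t]", line)]
            if parts[0].lower() in ("old", "oldname", "old_name"):
                continue
            rows.append((parts[0], parts[1] if len(parts) > 1 else ""))
    return rows


def build_hla_lexicon(
    allele_names: Iterable[str],
    history: Iterable[tuple[str, str]] = (),
    *,
    broad_antigens: Mapping[str, Iterable[str]] | None = None,
    haplotypes: Mapping[str, Iterable[str]] | None = None,
    generic_keywords: Iterable[str] = DEFAULT_GENERIC_KEYWORDS,
) -> AlleleSurfaceMap:
    """Compile the allele surface map.

    For every current allele, entries are generated at each field depth
    (HLA-B*13:01:02 also yields HLA-B*13:01 and HLA-B*13) so that lower
    resolution spellings in text resolve to a canonical of matching depth.
    History rows map retired names onto current canonicals; rows whose
    successor column is empty are retired outright and excluded from
    matching.  Broad-antigen groups, haplotypes and generic keywords come
    from configuration.
    """
    m = AlleleSurfaceMap()
    entry_cache: dict[str, AlleleEntry] = {}

    def current_entry(canon: str) -> AlleleEntry:
        if canon not in entry_cache:
            gene, fields = parse_allele_name(canon)
            entry_cache[canon] = AlleleEntry(canon, gene, fields, CATEGORY_CURRENT)
        return entry_cache[canon]

    for name in allele_names:
        gene, fields = parse_allele_name(name)
        for depth in range(1, len(fields) + 1):
            canon = canonical_name(gene, fields[:depth])
            entry = current_entry(canon)
            for s in surface_variants(canon):
                m.add(s, entry)

    for old, new in history:
        if not new:
            continue  # retired with no successor: excluded from matching
        gene, fields = parse_allele_name(new)
        canon = canonical_name(gene, fields)
        entry = AlleleEntry(canon, gene, fields, CATEGORY_OLD)
        for s in _literal_variants(old):
            m.add(s, entry)

    for group, members in (broad_antigens or {}).items():
        cands = tuple(members)
        gm = _SEROLOGY_RE.match(group)
        gene = gm.group("gene").upper() if gm else group
        fieldnum = (gm.group("field"),) if gm else ()
        entry = AlleleEntry(group, gene, fieldnum, CATEGORY_BROAD, cands)
        for s in _literal_variants(group):
            m.add(s, entry)

    for hap, members in (haplotypes or {}).items():
        entry = AlleleEntry(hap, hap, (), CATEGORY_HAPLOTYPE, tuple(members))
        for s in _literal_variants(hap):
            m.add(s, entry)

    for kw in generic_keywords:
        entry = AlleleEntry(kw, "HLA", (), CATEGORY_GENERIC)
        m.add(kw.lower(), entry)

    return m
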