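"""Drug-name lexicon merged from a SIDER-style TSV plus supplemental lists
(AFND, PharmGKB, local config), deduplicated case-insensitively with source
provenance retained."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DrugEntry:
    name: str
    sources: tuple[str, ...]
    adr_flag: bool = False


def read_sider_names(path: str) -> list[str]:
    """SIDER drug_names.tsv dialect: last tab-separated column is the name
    (first columns are compound IDs)."""
    names: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            name = line.split("\t")[-1].strip()
            if name and name.lower() != "name":
                names.append(name)
    return names


def build_drug_lexicon(
    sider_names: Iterable[str],
    extra_lists: Mapping[str, Iterable[str]] | None = None,
    *,
    adr_drugs: Iterable[str] = (),
) -> list[DrugEntry]:
    """Merge drug names across sources.

    Case-folded deduplication: a name present in several sources becomes one
    entry listing all of them.  ``adr_drugs`` flags names known to drive
    adverse drug reactions.  An empty input yields an empty lexicon with a
    warning.
    """
    by_key: dict[str, tuple[str, list[str]]] = {}

    def add(name: str, source: str) -> None:
        key = name.strip().lower()
        if not key:
            return
        if key not in by_key:
            by_key[key] = (name.strip(), [source])
        elif source not in by_key[key][1]:
            by_key[key][1].append(source)

    for n in sider_names:
        add(n, "SIDER")
    for source, names in (extra_lists or {}).items():
        for n in names:
            add(n, source)

    if not by_key:
        logger.warning("drug lexicon is empty")
        return []

    adr = {d.strip().lower() for d in adr_drugs}
    return [
        DrugEntry(name=name, sources=tuple(sources), adr_flag=key in adr)
        for key, (name, sources) in sorted(by_key.items())
    ]
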