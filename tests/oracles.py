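"""Independent brute-force oracles used to cross-check the fast matchers.

These deliberately avoid the implementation's compiled-regex path: keyword
hits come from repeated ``str.find`` over every lexicon surface, rsIDs from
a character-by-character scan.
"""

from __future__ import annotations

from hlalit.text import preprocess_variants


def brute_force_keyword_spans(
    text: str, surfaces, extra_word_chars: str = ""
) -> list[tuple[int, int]]:
    """All non-overlapping keyword spans (original offsets) under the
    boundary rule, resolved leftmost-longest; independent of the regex
    matcher.  Word characters are ASCII alphanumerics plus
    ``extra_word_chars`` ("*:" for alleles)."""
    st = preprocess_variants(text)

    def is_word(ch: str) -> bool:
        return ch.isascii() and ch.isalnum() or ch in extra_word_chars

    def boundary_ok(t: str, i: int, j: int) -> bool:
        return (i == 0 or not is_word(t[i - 1])) and (j == len(t) or not is_word(t[j]))

    candidates: set[tuple[int, int]] = set()
    lowered = {s.lower() for s in surfaces if s.strip()}
    for s in lowered:
        start = 0
        while True:
            i = st.text_a.find(s, start)
            if i < 0:
                break
            if boundary_ok(st.text_a, i, i + len(s)):
                candidates.add((i, i + len(s)))
            start = i + 1
    for s in lowered:
        sb = preprocess_variants(s).text_b
        if not sb:
            continue
        start = 0
        while True:
            i = st.text_b.find(sb, start)
            if i < 0:
                break
            if boundary_ok(st.text_b, i, i + len(sb)):
                candidates.add(st.span_b_to_original(i, i + len(sb)))
            start = i + 1

    ordered = sorted(candidates, key=lambda sp: (sp[0], -(sp[1] - sp[0])))
    out: list[tuple[int, int]] = []
    last_end = -1
    for i, j in ordered:
        if i >= last_end:
            out.append((i, j))
            last_end = j
    return out


def brute_force_rsids(text: str) -> list[str]:
    """Character-scan rsID extraction: 'r'/'R' then 's'/'S' then >=2 digits
    (maximal run); lowercased, first-occurrence order, deduplicated."""
    out: list[str] = []
    i = 0
    while i < len(text) - 3:
        if text[i] in "rR" and text[i + 1] in "sS":
            j = i + 2
            while j < len(text) and text[j].isdigit():
                j += 1
            if j - (i + 2) >= 2:
                rsid = "rs" + text[i + 2 : j]
                if rsid not in out:
                    out.append(rsid)
                i = j
                continue
        i += 1
    return out
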