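# Methods

This note documents the procedures implemented in `hlalit`, the parameters
that matter, the design choices made where the design was genuinely open,
and what the synthetic-corpus tests do and do not demonstrate.

## Input model

The unit of input is a PubMed-dialect XML citation. A record is usable when
it carries PMID, title, abstract text, publication date, journal and at
least one article type; authors are optional (`require_authors` flips
this). Records failing the check are skipped and counted, never repaired:
downstream statistics should not silently mix complete and partial records.

Structured-abstract labels (fourteen section names: background,
introduction, objective, method, experimental design, result, discussion,
importance, setting, design, study objective, patients, participants,
conclusion) are removed only where they function as labels — at the start
of the text or a line, or immediately after a sentence boundary, and only
when followed by a colon. This keeps the ordinary nouns ("our results
show…") intact. Plural label forms are accepted. Whether labels appear with
or without trailing colons in the wild is format-dependent; label+colon is
the default and the conservative choice, since a bare section word is
indistinguishable from prose.

Sentence offsets are 0-based half-open throughout; every `Sentence` slices
its cleaned abstract exactly. The splitter is an interface; the default is
rule-based (terminator followed by whitespace and an upper-case/digit
opener, with an abbreviation list and guards for initials and decimals) so
the core has no model dependency. Any callable returning spans can replace
it.

## Dictionaries

**Diseases.** Keywords come from an MRCONSO-dialect pipe-delimited table
restricted to MeSH (column indices configurable; defaults follow the
standard layout). Descriptor types ET, MH, PEP, DSV and PM are kept; DEV is
excluded because DEV strings are truncated forms ("abdominal inj") that
would only produce junk matches. Every keyword additionally emits a plural
and a lemmatized variant bound to the same descriptor ID, which is how
"tumors" finds D009369 without fuzzy matching. Tree numbers come from a
separate `mesh_id → label → tree number` table; the level-zero ancestor of
a tree number is its first dotted component, level-one the first two. The
level-one label (falling back to level-zero for top-level descriptors like
Neoplasms at C04) is what the rollup reports.

**HLA alleles.** For every allele name in the IMGT-style list, entries are
created at each field depth (`B*13:01:01` also yields `HLA-B*13:01` and
`HLA-B*13`), and for each canonical the full written-variant set is
generated: {with/without `HLA-` prefix} × {`*`, `(*)`, no star} ×
{with/without `:` separators}. This covers the five spellings observed for
one allele in practice (`HLA-B*13:01`, `HLA-B*1301`, `B*1301`, `B(*)1301`,
`B1301`) as well as serology-style forms (`HLA-B27`). Retired names map
through the old→current history table; a history row with no successor is
dropped from matching entirely. Serological broad-antigen groups (one
surface, ≥2 candidate alleles) and multi-allele haplotypes ship as editable
YAML because no authoritative public table exists; surfaces resolving
through them come back flagged ambiguous with all candidates, and no
locus-priority guessing is attempted. Canonical output format is fixed to
the current colon-delimited form with the `HLA-` prefix. `collapse_two_digit`
truncates to locus + first field and is idempotent; generic keywords
("HLA class I" …) are matchable but not collapsible.

**Drugs.** Names are merged case-insensitively across a SIDER-style TSV and
supplemental lists, keeping per-source provenance. Nothing
pharmacological is modeled; the lexicon is a string set.

## Matching

Both search variants of each sentence are scanned: variant A is the
lowercased original; variant B lowercases and strips special characters
(hyphens → space; apostrophes, parentheses, `*`, `:` deleted) with a total,
strictly increasing position map back to original offsets. This is what
lets "Stevens Johnson syndrome" hit the hyphenated keyword and vice versa,
with offsets still anchored in the original sentence.

A hit must be flanked by non-word characters. For alleles the word class is
`[A-Za-z0-9*:]` — standard `\b` would accept the boundary inside
`4B1301X`'s neighborhood next to `*` — for diseases and drugs it is plain
alphanumeric. Overlapping hits resolve longest-match-wins with leftmost
tie-breaking, applied after merging A- and B-variant hits (A preferred on
identical spans). The matcher compiles one longest-first alternation regex
per variant; the test suite checks it against a brute-force `str.find`
scanner on randomized sentences, so the fast path and the definition are
kept separate.

Screening keeps an abstract when title+abstract jointly contain at least
one allele surface and one disease keyword; sentence retention then
requires both kinds in the *same* sentence. Title text screens but is not
annotated (titles are headlines, not claims); this is configurable.

## Secondary taggers

rsIDs follow the case-insensitive pattern `rs` + ≥2 digits with no upper
bound on length, reported lowercased, deduplicated, in first-occurrence
order. A drug hit whose span is contained in a disease-mention span is
discarded as a fragment of the disease name. Population tagging runs over
the whole abstract — cohort descriptions rarely share a sentence with the
association claim — through an injected token-classification backend; only
NORP-class entities are kept because GPE output over biomedical text is
dominated by organism names misread as places. Surfaces are case-folded,
singularized and binned through curated demonym→country and ethnic-group
tables; unmapped surfaces are flagged `unbinned` rather than guessed. The
default backend is a gazetteer over those same tables, so the offline
pipeline is self-consistent; a model-based backend can be injected through
the same two-method interface.

## Semantic labeling

Stage 1 scans token n-grams (n ≤ 3, raw and lemmatized) against the cue
lexicon and sets three presence bits. The negation scope is whole-sentence
presence of `not`/`none`/`no` — crude but predictable; clause-level scoping
is out of scope. The carrier-status guard excludes the tokens
`positive`/`negative` within `guard_k` tokens (default 2) after an allele
mention from cue matching, so "HLA-B27 negative patients" cannot by itself
drive a Negative label.

The coding vector maps to a stage-1 label by an explicit total table: one
polarity alone keeps its name; both polarities → complex (negation does not
rescue it); one polarity + negation → ambiguous; negation alone → negation;
nothing → others. The table is this package's definition, chosen to match
the named outcome classes and to stay stringent about negative calls.

Stage 2 masks allele mentions as `@GENE` and disease mentions as
`@DISEASE` (right-to-left so offsets stay valid; overlapping mentions are a
hard error since upstream resolution must have removed them) — masking
exists because multi-word entities otherwise fragment under tokenization.
The root verb comes from an injected parser interface; the default is a
flat POS heuristic: a sentence opening with a to-infinitive roots at that
infinitive and defaults to the investigatory class, otherwise the first
non-auxiliary verb-tagged token is the root ("was associated with" roots at
"associated" → lemma "associate"). Verb→class assignments (positive /
negative / investigatory) load from an editable TSV.

The final decision table requires stage-1/verb agreement for a polar call:
(positive, positive) → Positive, (negative, negative) → Negative; complex
stays Complex; ambiguous and negation-only fold into Ambiguous (the final
scheme has six classes and no separate negation class); an investigatory
verb converts any unresolved polarity into Investigatory; everything else,
including outright disagreement (stage-1 positive with a negative verb), is
Others — disagreement is evidence of a complicated sentence, not of either
polarity.

`build_ngram_candidates` is the curation aid that produced such cue tables
in the first place: stopword-filtered, lemmatized verb/adverb unigrams and
adverb-verb bigrams/trigrams above a frequency cut-off (default 10,
configurable; ranked by count, ties lexicographic). Its output is meant for
manual review, not direct use.

## Categories and export

Category rules operate on MeSH tree positions of disease mentions plus
sentence co-mentions, as listed in the README. The ADR tree prefix defaults
to the chemically-induced-disorders subtree (`C25.723`) and is
configurable. Multi-category membership is the default; an exclusive mode
keeps the highest-priority category (ADR > Transplantation > Signs &
Symptoms > Diseases) for workflows that need disjoint counts. Mentions
without tree numbers are ignored for categorization and logged. All export
tables are UTF-8 TSV with fixed column order and row sort, so identical
inputs produce byte-identical files; `import_tables` is the lossless
inverse.

## Synthetic corpus and what the tests show

The fixture generator plants sentences from fourteen slot-filled templates
(positive, negative, negation, ambiguous, investigatory, complex, others,
carrier-guard, two ADR shapes, transplantation, signs-and-symptoms, rsID,
drug-in-disease-name, broad-antigen), fills them from pools that the
generated mini-lexicons cover exactly, and serializes the complete truth —
every mention with offsets, every sentence's stage-1 and final label, every
abstract's categories, populations and rsIDs. Truth categories are
re-derived inside the generator from the planted slots and a literal tree
table, not by calling the categorizer. Defaults are 200 abstracts,
~1.65 planted sentences each plus optional no-entity filler, all sampling
driven by one seed; the same seed reproduces the corpus byte for byte.

Because templates are constructed inside lexicon coverage, end-to-end
precision and recall of 1.0 demonstrate *internal consistency* — that
normalization, boundary matching, guard logic, labeling and categorization
compose without loss — and they are sensitive to regressions in any stage.
They do not estimate performance on real abstracts, where cue vocabulary
coverage, parser quality and dictionary completeness dominate and where the
curated tables shipped here are stand-ins: the cue lexicon
(`label_lexicon_synthetic.tsv`) reproduces the documented structure and
size of its curated counterpart (1,107 positive / 20 negative verb/adverb
surfaces) but was generated combinatorially from seed verb and adverb
lists, and the population and broad-antigen tables are seeded from a
handful of published examples. All three are plain TSV/YAML precisely so a
curation pass can replace them without code changes.

## Numerical and degenerate-input choices

No stage draws randomness; the only RNG in the package is the fixture
generator's, fully determined by its seed. Ties in every ranking are broken
lexicographically. Empty inputs degrade without raising: an empty abstract
yields no sentences, an empty drug table an empty (warned) lexicon, a
missing NER backend empty population tags, an empty corpus header-only
exports. Hard errors are reserved for malformed XML (with parser position),
unknown lookup keys, overlapping mention spans at masking time and invalid
configuration (empty n-gram sets, cut-off < 1, overlapping cue polarity
sets).

## Known limitations

- Cue detection is presence-based; it has no clause scoping, so a negation
  anywhere in the sentence marks the whole sentence.
- The default root-verb finder is a heuristic, not a parse; garden-path
  sentences will mislabel. The interface accepts a real dependency parser.
- Allele ambiguity is reported, not resolved: broad-antigen surfaces return
  candidate sets and it is the consumer's job to decide.
- Mentions are sentence-local; there is no coreference across sentences, so
  "this allele was also protective…" is invisible to the labeler.
- Expression-variant suffixes on allele names (N/L/Q etc.) are parsed but
  carry no semantics.
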