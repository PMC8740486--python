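# hlalit

Dictionary-based mining of HLA allele–disease associations from
MEDLINE/PubMed abstracts.

The human leukocyte antigen (HLA) locus is the most polymorphic region of
the human genome, and thousands of papers report that particular alleles
confer risk for, or protection from, autoimmune disease, infection,
transplant outcomes and adverse drug reactions (e.g. HLA-B\*57:01 and
abacavir hypersensitivity, HLA-B\*15:02 and carbamazepine-induced
Stevens-Johnson syndrome). Reading that literature programmatically is
harder than it sounds: the same allele is written `HLA-B*13:01`,
`HLA-B*1301`, `B*1301`, `B(*)1301` or `B1301` depending on the paper, the
same disease hides behind dozens of MeSH entry terms, and a sentence like
"HLA-B27 negative patients…" refers to carrier status, not to a negative
association.

`hlalit` is a self-contained pipeline for this curation problem, aimed at
immunogenetics and pharmacogenomics groups who want structured
allele/disease/SNP/drug/population annotations out of raw abstract XML:

1. **medline** — parse PubMed-dialect XML, keep only complete records,
   strip structured-abstract labels (`BACKGROUND:`, `RESULTS:` …), split
   sentences with exact character offsets.
2. **lexicons** — compile the three keyword dictionaries: MeSH disease
   keywords from an MRCONSO-dialect concept table (descriptor types
   ET/MH/PEP/DSV/PM; DEV excluded) with the tree hierarchy; an HLA allele
   surface map that enumerates every recognized spelling of every allele
   (including retired names mapped through the naming history, serology
   "broad antigen" groups and haplotypes); drug names merged from
   SIDER-style plus supplemental lists.
3. **matching** — boundary-aware, case-insensitive dictionary NER over two
   search variants (with and without special characters), longest match
   wins; abstracts are screened for ≥1 allele and ≥1 disease, and only
   sentences co-mentioning both are retained.
4. **taggers** — dbSNP rsIDs (`rs` + ≥2 digits), drug mentions with a
   containment filter (no "insulin" inside "insulin dependent diabetes
   mellitus"), and population/ethnicity tags via a pluggable NORP/GPE
   token-classification backend (default: offline gazetteer).
5. **semantics** — hybrid polarity labeling. Stage 1 scans for curated
   positive/negative cue phrases and negation words (`not`, `none`, `no`)
   into a binary coding vector `(pos, neg, negation)`; a carrier-status
   guard keeps "\<allele\> negative/positive" out of the cue counts. Stage 2
   masks entities as `@GENE`/`@DISEASE`, extracts the root verb and looks up
   its polarity class. The two signals combine into one of six labels:
   Positive, Negative, Complex, Ambiguous, Investigatory, Others.
6. **categorize** — assign abstracts to study categories from MeSH tree
   positions (C23 → Signs & Symptoms; C20.452/E04 → Transplantation;
   drug+allele+disease co-mention with an ADR cue → Therapeutics/ADR;
   remaining C-branch → Diseases) and export all tables as deterministic
   TSV/JSON.
7. **fixtures** — a seeded generator of miniature PubMed-dialect corpora
   and lexicon source files with *planted* ground truth, so the whole
   pipeline is testable offline, end to end, with exact precision/recall.

## Worked example

```python
from hlalit.fixtures import FixtureSpec, generate_corpus, fixture_pipeline_config
from hlalit.config import build_resources
from hlalit.medline import parse_medline
from hlalit.pipeline import Pipeline

spec = FixtureSpec(n_abstracts=12, seed=4)
fx = generate_corpus(spec, "demo/corpus")                 # PubMed-dialect XML + truth tables
cfg = fixture_pipeline_config("demo/lexicons")            # mini allele list, MRCONSO, MeSH tree, drugs
pipeline = Pipeline(build_resources(cfg))
bundle = pipeline.run(parse_medline(fx.xml_path).records).export_bundle()
print(bundle.summary)
```

prints

```
{'n_abstracts': 12, 'n_sentences_labeled': 22, 'n_mentions': 47,
 'n_snp_mentions': 1,
 'label_counts': {'Ambiguous': 4, 'Complex': 1, 'Investigatory': 2,
                  'Negative': 2, 'Others': 3, 'Positive': 10},
 'category_counts': {'Diseases': 12, 'SignsSymptoms': 1,
                     'TherapeuticsADR': 2, 'Transplantation': 1}}
```

i.e. all 12 synthetic abstracts survive allele+disease screening, their 22
co-occurrence sentences get semantic labels (10 positive associations, 2
protective, 4 ambiguous/negated, …), and each abstract lands in its study
categories. The mention table normalizes every planted spelling back to a
canonical name:

```
    pmid        surface      canonical
10000001         B*5701    HLA-B*57:01
10000001         B*1502    HLA-B*15:02
10000002          B1301    HLA-B*13:01
10000002 HLA-DQB1*06:02 HLA-DQB1*06:02
```

The same run is available from the shell:

```bash
hlalit simulate --n-abstracts 12 --seed 4 -o demo/
hlalit mine demo/corpus.xml -c config.yaml -o out/
hlalit summarize out/
```

## Layout

```
src/hlalit/          library (medline, lexicons/, matching, taggers,
                     semantics, categorize, pipeline, fixtures, config, cli)
src/hlalit/data/     shipped rule tables (semantic cue lexicon, verb
                     polarity, stopwords, population binning, HLA groups)
tests/               pytest suite incl. brute-force oracles and the
                     acceptance checks
scripts/acceptance.py
docs/methods.md      model, assumptions, parameter choices, limitations
```

Note on shipped tables: the semantic cue lexicon
(`data/label_lexicon_synthetic.tsv`) and the population/HLA-group tables are
synthetic stand-ins with the documented structure and counts of their
curated counterparts; see `docs/methods.md` for what that does and does not
imply about behavior on real text.
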