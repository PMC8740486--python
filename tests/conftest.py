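"""Shared fixtures: a seeded miniature corpus, compiled resources and a
ready pipeline, all generated programmatically at test time."""

from __future__ import annotations

import pytest

from hlalit.config import build_resources
from hlalit.fixtures import FixtureSpec, fixture_pipeline_config, generate_corpus
from hlalit.medline import parse_medline
from hlalit.pipeline import Pipeline


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("fixture")


@pytest.fixture(scope="session")
def corpus(fixture_dir):
    spec = FixtureSpec(n_abstracts=60, seed=11, n_incomplete=2)
    return generate_corpus(spec, str(fixture_dir / "corpus"))


@pytest.fixture(scope="session")
def resources(fixture_dir):
    cfg = fixture_pipeline_config(str(fixture_dir / "lexicons"))
    return build_resources(cfg)


@pytest.fixture(scope="session")
def pipeline(resources):
    return Pipeline(resources)


@pytest.fixture(scope="session")
def parsed_records(corpus):
    return parse_medline(corpus.xml_path).records


def make_sentence(text: str, pmid: str = "1", index: int = 0):
    from hlalit.types import Sentence

    return Sentence(record_pmid=pmid, index=index, text=text,
                    char_start=0, char_end=len(text))
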