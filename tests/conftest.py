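"""Shared fixtures: the bundled flowchart, deterministic backends, lookup
tables, and an end-to-end pipeline runner over synthetic articles."""

import pytest

from goflow.articles import parse_jats
from goflow.backends import KeywordBackend
from goflow.corpus import load_urs_table
from goflow.engine import run_flowchart
from goflow.flowchart import load_bundled_flowchart
from goflow.synth import KEYWORD_RULES, SYNTH_UNIPROT_TABLE, SYNTH_URS_TABLE
from goflow.targets import GeneMentionList, load_uniprot_table


@pytest.fixture(scope="session")
def fc():
    return load_bundled_flowchart()


@pytest.fixture(scope="session")
def keyword_backend():
    return KeywordBackend.from_file(KEYWORD_RULES)


@pytest.fixture(scope="session")
def urs_table():
    return load_urs_table(SYNTH_URS_TABLE)


@pytest.fixture(scope="session")
def uniprot_table():
    return load_uniprot_table(SYNTH_UNIPROT_TABLE)


@pytest.fixture(scope="session")
def run_item(fc, keyword_backend, urs_table, uniprot_table):
    """Run one synthetic CorpusItem through filter-free curation and
    return (article, record)."""

    def _run(item, **overrides):
        article = parse_jats(item.xml)
        mentions = GeneMentionList(
            pmcid=article.pmcid,
            symbols=[a["exact"] for a in item.gene_fixture[0]["annotations"]],
        )
        kwargs = dict(
            gene_mentions=mentions,
            urs_lookup=urs_table,
            uniprot_lookup=uniprot_table,
        )
        kwargs.update(overrides)
        record = run_flowchart(article, fc, keyword_backend, **kwargs)
        return article, record

    return _run
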