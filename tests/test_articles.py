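"""JATS parsing, heading normalization, and budgeted section loading."""

import xml.etree.ElementTree as stdlib_etree

import pytest
from hypothesis import given, settings, strategies as st

from goflow.articles import (
    Article,
    ContextBudget,
    SectionCache,
    get_section,
    normalize_headings,
    parse_jats,
)
from goflow.backends import ScriptedBackend, count_tokens
from goflow.errors import ArticleParseError, BudgetExhausted
from goflow.synth import SynthSpec, generate_article


def make_jats(headings_bodies, article_type="research-article", abstract="An abstract."):
    secs = "".join(
        f"<sec><title>{h}</title><p>{b}</p></sec>" for h, b in headings_bodies
    )
    return (
        f'<article article-type="{article_type}"><front><article-meta>'
        f'<article-id pub-id-type="pmcid">PMC1</article-id>'
        f'<article-id pub-id-type="pmid">11</article-id>'
        f"<title-group><article-title>T</article-title></title-group>"
        f"<abstract><p>{abstract}</p></abstract>"
        f"</article-meta></front><body>{secs}</body></article>"
    ).encode()


# ---------------------------------------------------------------------------
# Parsing


def test_headings_round_trip():
    xml = make_jats(
        [("Background", "a"), ("MATERIALS AND METHODS", "b"), ("Findings", "c")]
    )
    art = parse_jats(xml)
    assert art.headings() == ["Background", "MATERIALS AND METHODS", "Findings"]
    assert art.pmcid == "PMC1" and art.pmid == "11"


def test_nested_sec_folded_depth_first():
    xml = (
        b'<article article-type="research-article"><front><article-meta>'
        b'<article-id pub-id-type="pmcid">PMC2</article-id>'
        b"<title-group><article-title>T</article-title></title-group>"
        b"</article-meta></front><body>"
        b"<sec><title>Results</title><p>alpha</p>"
        b"<sec><title>Sub</title><p>beta</p><sec><title>SubSub</title><p>gamma</p></sec></sec>"
        b"<p>delta</p></sec>"
        b"</body></article>"
    )
    art = parse_jats(xml)
    assert len(art.sections) == 1
    body = art.sections[0][1]
    # independent oracle: stdlib depth-first text walk of the <sec> element
    expected_order = [
        t.strip()
        for t in stdlib_etree.fromstring(xml).find("body/sec").itertext()
        if t.strip() and t.strip() != "Results"
    ]
    positions = [body.find(tok) for tok in ["alpha", "beta", "gamma", "delta"]]
    assert all(p >= 0 for p in positions)
    assert positions == sorted(positions)
    assert [t for t in expected_order if t in ("alpha", "beta", "gamma", "delta")] == [
        "alpha", "beta", "gamma", "delta",
    ]


def test_pub_types_from_article_type_attribute():
    art = parse_jats(make_jats([("Results", "x")], article_type="review-article"))
    assert "review-article" in art.pub_types


def test_bodyless_document_fails_with_pmcid():
    xml = (
        b'<article article-type="research-article"><front><article-meta>'
        b'<article-id pub-id-type="pmcid">PMC9</article-id>'
        b"</article-meta></front></article>"
    )
    with pytest.raises(ArticleParseError) as ei:
        parse_jats(xml)
    assert ei.value.pmcid == "PMC9"


def test_non_xml_fails():
    with pytest.raises(ArticleParseError):
        parse_jats(b"this is not xml at all")


def test_section_bodies_are_subsequences_of_xml_text():
    """Parsing never invents characters: every body word occurs in the
    raw XML text nodes, in order."""
    for seed in range(5):
        spec = SynthSpec(outcome="term_0035279", seed=seed)
        xml, _, _ = generate_article(spec)
        art = parse_jats(xml)
        raw_text = " ".join(
            t for t in stdlib_etree.fromstring(xml).itertext()
        )
        for _, body in art.sections:
            for word in body.split():
                assert word in raw_text


# ---------------------------------------------------------------------------
# Heading normalization


def test_normalize_headings_shouty_methods():
    art = parse_jats(
        make_jats([("MATERIALS AND METHODS", "m"), ("RESULTS", "r")])
    )
    backend = ScriptedBackend(
        {
            "heading:abstract": "NONE",
            "heading:introduction": "NONE",
            "heading:methods": "MATERIALS AND METHODS",
            "heading:results": "RESULTS",
            "heading:discussion": "NONE",
        }
    )
    index = normalize_headings(art, backend)
    assert index == {"methods": "MATERIALS AND METHODS", "results": "RESULTS"}


def test_normalize_headings_identity():
    heads = ["Abstract", "Introduction", "Methods", "Results", "Discussion"]
    art = parse_jats(make_jats([(h, "x") for h in heads]))
    backend = ScriptedBackend(
        {f"heading:{lbl}": h for lbl, h in zip(
            ("abstract", "introduction", "methods", "results", "discussion"), heads
        )}
    )
    index = normalize_headings(art, backend)
    assert index == dict(
        zip(("abstract", "introduction", "methods", "results", "discussion"), heads)
    )


def test_normalize_headings_is_injective_by_construction(fc, keyword_backend):
    art = parse_jats(make_jats([("Results and Discussion", "x"), ("Other", "y")]))
    index = normalize_headings(art, keyword_backend)
    assert len(set(index.values())) == len(index)


def test_none_sentinel_leaves_label_absent():
    art = parse_jats(make_jats([("Weird Heading", "x")]))
    backend = ScriptedBackend(
        {f"heading:{lbl}": "NONE" for lbl in
         ("abstract", "introduction", "methods", "results", "discussion")}
    )
    index = normalize_headings(art, backend)
    assert "methods" not in index


# ---------------------------------------------------------------------------
# Budgeted lazy loading


def make_article(results_paras=10, words_per_para=8):
    body = "\n".join(
        " ".join(f"w{i}_{j}" for j in range(words_per_para))
        for i in range(results_paras)
    )
    return Article(
        pmcid="PMC1", pmid="1", title="T", pub_types={"research-article"},
        sections=[("Results", body)], abstract="short abstract text",
    )


def test_get_section_idempotent_and_charged_once():
    art = make_article()
    cache = SectionCache(budget=ContextBudget())
    index = {"results": "Results"}
    a = get_section(art, "results", index, cache)
    charged = cache.charged_tokens
    b = get_section(art, "results", index, cache)
    assert a == b
    assert cache.charged_tokens == charged
    assert len(cache.log) == 1


def test_truncation_ends_at_paragraph_boundary():
    art = make_article(results_paras=10, words_per_para=8)
    budget = ContextBudget(max_context_tokens=30, max_evidence_source_tokens=10)
    cache = SectionCache(budget=budget)
    text = get_section(art, "results", {"results": "Results"}, cache)
    # independent oracle: greedy paragraph packing under the token counter
    paras = art.sections[0][1].split("\n")
    expected, used = [], 0
    for p in paras:
        if used + count_tokens(p) > 30:
            break
        expected.append(p)
        used += count_tokens(p)
    assert text == "\n".join(expected)
    assert art.sections[0][1].startswith(text)
    assert cache.log[0].truncated


def test_absent_label_falls_back_to_body_and_flags():
    art = make_article()
    art.abstract = ""
    cache = SectionCache(budget=ContextBudget())
    text = get_section(art, "methods", {}, cache)
    assert text == art.body_text()
    assert cache.log[0].fallback


def test_budget_exhaustion_raises():
    art = make_article(results_paras=1, words_per_para=50)
    budget = ContextBudget(max_context_tokens=10, max_evidence_source_tokens=5)
    cache = SectionCache(budget=budget)
    with pytest.raises(BudgetExhausted):
        get_section(art, "results", {"results": "Results"}, cache)


# ---------------------------------------------------------------------------
# Token counting


def test_count_tokens_basics():
    assert count_tokens("") == 0
    n = count_tokens("miR-21 represses PTEN")
    assert n == 3 and count_tokens("miR-21 represses PTEN") == n


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.text(max_size=60), st.text(max_size=60))
def test_count_tokens_concatenation_property(a, b):
    """Monotone under concatenation; join differs from the sum by at most
    one fused token."""
    ab = count_tokens(a + b)
    assert ab >= max(count_tokens(a), count_tokens(b))
    assert abs(ab - (count_tokens(a) + count_tokens(b))) <= 1
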