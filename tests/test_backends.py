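"""Constrained-generation contract: verifiers, scripted and keyword backends."""

import random
import re

import pytest

from goflow.backends import (
    Backend,
    ChoiceRequest,
    ChoiceResponse,
    KeywordBackend,
    KeywordRule,
    ScriptedBackend,
    SpanRequest,
    SpanResponse,
    choose,
    extract_span,
    truncate_to_tokens,
)
from goflow.errors import ContractViolation, ScriptError


class OffListBackend(Backend):
    name = "off-list"

    def _choose(self, req):
        return ChoiceResponse(selected="maybe", reasoning="", reasoning_tokens_used=0)


class ParaphraseBackend(Backend):
    """Adversarial: claims offsets but returns a paraphrase."""

    name = "paraphrase"

    def _extract_span(self, req):
        return SpanResponse(span="a paraphrase of the text", start=0, end=25)


class OverBudgetBackend(Backend):
    name = "over-budget"

    def _choose(self, req):
        return ChoiceResponse(
            selected=req.options[0], reasoning="x " * 5000,
            reasoning_tokens_used=5000,
        )


# ---------------------------------------------------------------------------
# Request validation


def test_choice_request_rejects_empty_and_duplicate_options():
    with pytest.raises(ValueError):
        ChoiceRequest(key="k", prompt="p", options=())
    with pytest.raises(ValueError):
        ChoiceRequest(key="k", prompt="p", options=("yes", "yes"))


# ---------------------------------------------------------------------------
# Scripted backend


def test_scripted_choice_and_determinism():
    b = ScriptedBackend({"node1": "yes"})
    req = ChoiceRequest(key="node1", prompt="p", options=("yes", "no"))
    r1, r2 = choose(b, req), choose(b, req)
    assert r1.selected == "yes"
    assert r1 == r2  # byte-identical responses across runs


def test_scripted_missing_key_names_it():
    b = ScriptedBackend({"node1": "yes"})
    with pytest.raises(ScriptError, match="node2"):
        choose(b, ChoiceRequest(key="node2", prompt="p", options=("yes", "no")))


def test_scripted_span_returns_exact_slice():
    source = "First sentence here. Second sentence there."
    b = ScriptedBackend({"n": [21, 43]})
    resp = extract_span(b, SpanRequest(key="n", prompt="p", source=source))
    assert resp.span == "Second sentence there."
    assert source[resp.start : resp.end] == resp.span


def test_forced_single_option():
    b = ScriptedBackend({"n": "yes"})
    resp = choose(b, ChoiceRequest(key="n", prompt="p", options=("yes",)))
    assert resp.selected == "yes"


# ---------------------------------------------------------------------------
# Contract violations


def test_off_list_choice_raises_naming_backend():
    with pytest.raises(ContractViolation, match="off-list"):
        choose(
            OffListBackend(),
            ChoiceRequest(key="n", prompt="p", options=("yes", "no")),
        )


def test_paraphrase_span_rejected():
    with pytest.raises(ContractViolation, match="verbatim"):
        extract_span(
            ParaphraseBackend(),
            SpanRequest(key="n", prompt="p", source="completely different source text here"),
        )


def test_reasoning_over_cap_rejected():
    with pytest.raises(ContractViolation, match="reasoning_tokens_used"):
        choose(
            OverBudgetBackend(),
            ChoiceRequest(key="n", prompt="p", options=("yes", "no")),
        )


def test_empty_source_after_truncation_is_precondition_error():
    b = ScriptedBackend({"n": [0, 1]})
    with pytest.raises(ValueError):
        extract_span(b, SpanRequest(key="n", prompt="p", source="   "))


def test_span_verifier_fuzz():
    """Randomized scripted spans: every accepted response is the exact
    half-open slice; out-of-range scripts raise before acceptance."""
    rng = random.Random(0)
    source = " ".join(f"tok{i}." for i in range(200))
    accepted = 0
    for _ in range(1000):
        start = rng.randrange(0, len(source) - 1)
        end = rng.randrange(start + 1, min(start + 200, len(source)) + 1)
        b = ScriptedBackend({"n": [start, end]})
        resp = extract_span(
            b, SpanRequest(key="n", prompt="p", source=source, max_span_chars=200)
        )
        assert source[resp.start : resp.end] == resp.span
        accepted += 1
    assert accepted == 1000


# ---------------------------------------------------------------------------
# Keyword backend


RULES = [
    KeywordRule(pattern=r"(?i)luciferase reporter", scope="reporter_assay", answer="yes"),
    KeywordRule(pattern=r"(?i)qRT-PCR[^.]*decreas", scope="mrna_level", answer="yes"),
]


def test_keyword_rule_match_and_default():
    b = KeywordBackend(RULES)
    yes = choose(
        b,
        ChoiceRequest(
            key="reporter_assay",
            prompt="Q?\n\n--- article section: results ---\nA luciferase reporter assay was used.",
            options=("yes", "no"),
        ),
    )
    assert yes.selected == "yes"
    no = choose(
        b,
        ChoiceRequest(
            key="reporter_assay",
            prompt="Q?\n\n--- article section: results ---\nOnly northern blots were used.",
            options=("yes", "no"),
        ),
    )
    assert no.selected == "no"


def test_keyword_rules_do_not_match_node_guidance():
    """Guidance text names the assays; only the article section may
    trigger a rule."""
    b = KeywordBackend(RULES)
    resp = choose(
        b,
        ChoiceRequest(
            key="reporter_assay",
            prompt=(
                "Acceptable assays include luciferase reporter assays.\n\n"
                "--- article section: results ---\nNo assays reported."
            ),
            options=("yes", "no"),
        ),
    )
    assert resp.selected == "no"


def test_keyword_rule_order_is_semantics():
    overlapping = [
        KeywordRule(pattern=r"(?i)assay", scope="n", answer="no"),
        KeywordRule(pattern=r"(?i)luciferase", scope="n", answer="yes"),
    ]
    b = KeywordBackend(overlapping)
    req = ChoiceRequest(
        key="n",
        prompt="--- article section: results ---\nA luciferase assay.",
        options=("yes", "no"),
    )
    assert choose(b, req).selected == "no"
    b2 = KeywordBackend(list(reversed(overlapping)))
    assert choose(b2, req).selected == "yes"


def test_empty_rule_list_defaults_no():
    b = KeywordBackend([])
    resp = choose(b, ChoiceRequest(key="any", prompt="p", options=("yes", "no")))
    assert resp.selected == "no"


def test_keyword_span_is_first_matching_sentence():
    source = (
        "Cells were cultured overnight. A luciferase reporter gene fused to "
        "the 3'UTR of PTEN showed reduced activity. Controls behaved as expected."
    )
    b = KeywordBackend(RULES)
    resp = extract_span(
        b, SpanRequest(key="reporter_assay", prompt="p", source=source)
    )
    # independent oracle: naive sentence split + first regex hit
    sentences = re.split(r"(?<=[.!?])\s+", source)
    expected = next(
        s for s in sentences if re.search(r"(?i)luciferase reporter", s)
    )
    assert resp.span == expected
    assert source[resp.start : resp.end] == resp.span


def test_truncate_to_tokens_is_prefix():
    text = "one two three four five"
    t = truncate_to_tokens(text, 3)
    assert text.startswith(t)
    assert t.split() == ["one", "two", "three"]
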