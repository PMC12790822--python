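"""Constrained-generation backend contract and model-free backends.

Every backend — whether a real constrained-decoding language model or a
test double — satisfies the same observable contract:

* :func:`choose` always returns one of the offered options, verbatim
  (mirrors constrained decoding that masks the token space down to the
  option set), with a bounded reasoning trace.
* :func:`extract_span` always returns a verbatim substring of the offered
  source text with 0-based half-open character offsets.

The contract is enforced by shared verifier wrappers, never trusted to
adapters: a backend that returns an off-list option or a paraphrased span
raises :class:`~goflow.errors.ContractViolation` before anything reaches
the curation engine.

Two deterministic backends are provided: :class:`ScriptedBackend` (an
explicit key -> answer table for replay and unit tests) and
:class:`KeywordBackend` (an ordered regex rule table standing in for a
reasoning model on synthetic articles).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

from .errors import ContractViolation, ScriptError

DEFAULT_REASONING_CAP = 1024

#: Request-key prefix for zero-shot heading normalization.
HEADING_KEY_PREFIX = "heading:"
#: Request key for the target-gene selection loop.
TARGET_SELECT_KEY = "target_select"
#: Sentinels used in constrained choices.
NONE_SENTINEL = "NONE"
DONE_SENTINEL = "DONE"
NOT_IN_LIST_SENTINEL = "NOT_IN_LIST"

#: Delimiter separating node guidance from article text in assembled
#: prompts; rule backends match article text only, never the guidance
#: (which itself names the assay vocabulary).
SECTION_DELIM = "--- article section:"


def count_tokens(text: str) -> int:
    """Deterministic whitespace token count (the model-free default).

    Monotone under concatenation; ``count(a + b)`` differs from
    ``count(a) + count(b)`` by at most one (a join may fuse two tokens).
    """
    return len(text.split())


# ---------------------------------------------------------------------------
# Request / response types


@dataclass(frozen=True)
class ChoiceRequest:
    """A constrained choice among a fixed option list.

    ``key`` identifies the decision point (a flowchart node id, a
    ``heading:<label>`` normalization request, or the target-selection
    loop) so deterministic backends can be scripted per decision.
    """

    key: str
    prompt: str
    options: Tuple[str, ...]
    reasoning_cap: int = DEFAULT_REASONING_CAP
    temperature: float = 0.0

    def __post_init__(self):
        if not self.options:
            raise ValueError("options must be non-empty")
        if len(set(self.options)) != len(self.options):
            raise ValueError("options must be pairwise distinct")
        if self.reasoning_cap <= 0:
            raise ValueError("reasoning_cap must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")


@dataclass(frozen=True)
class ChoiceResponse:
    selected: str
    reasoning: str = ""
    reasoning_tokens_used: int = 0


@dataclass(frozen=True)
class SpanRequest:
    """Ask for a verbatim evidence substring of ``source``.

    ``source`` is truncated to a ``max_source_tokens`` prefix before the
    backend sees it, so returned offsets remain valid into the full text.
    """

    key: str
    prompt: str
    source: str
    max_source_tokens: int = 4000
    max_span_chars: int = 600


@dataclass(frozen=True)
class SpanResponse:
    span: str
    start: int
    end: int
    reasoning: str = ""


class Backend:
    """Adapter interface. Subclasses implement the underscore methods;
    callers go through the module-level :func:`choose` / :func:`extract_span`
    verifiers."""

    name = "abstract"

    def _choose(self, req: ChoiceRequest) -> ChoiceResponse:  # pragma: no cover
        raise NotImplementedError

    def _extract_span(self, req: SpanRequest) -> SpanResponse:  # pragma: no cover
        raise NotImplementedError


# ---------------------------------------------------------------------------
# Contract verifiers


def choose(backend: Backend, req: ChoiceRequest) -> ChoiceResponse:
    """Run a constrained choice and verify the contract."""
    resp = backend._choose(req)
    if resp.selected not in req.options:
        raise ContractViolation(
            f"choice {resp.selected!r} not in options {list(req.options)!r} "
            f"(key={req.key})",
            backend=backend.name,
        )
    if resp.reasoning_tokens_used < 0 or resp.reasoning_tokens_used > req.reasoning_cap:
        raise ContractViolation(
            f"reasoning_tokens_used={resp.reasoning_tokens_used} outside "
            f"[0, {req.reasoning_cap}] (key={req.key})",
            backend=backend.name,
        )
    return resp


def truncate_to_tokens(text: str, max_tokens: int) -> str:
    """Longest prefix of *text* containing at most *max_tokens* whitespace
    tokens. A prefix, so character offsets into it are offsets into *text*."""
    if max_tokens <= 0:
        return ""
    count = 0
    for m in re.finditer(r"\S+", text):
        count += 1
        if count == max_tokens:
            return text[: m.end()]
    return text


def extract_span(backend: Backend, req: SpanRequest) -> SpanResponse:
    """Run a constrained span extraction and verify offsets byte-exactly."""
    source = truncate_to_tokens(req.source, req.max_source_tokens)
    if not source.strip():
        raise ValueError("span source empty after truncation")
    eff = SpanRequest(
        key=req.key,
        prompt=req.prompt,
        source=source,
        max_source_tokens=req.max_source_tokens,
        max_span_chars=req.max_span_chars,
    )
    resp = backend._extract_span(eff)
    if not (0 <= resp.start < resp.end <= len(source)):
        raise ContractViolation(
            f"span offsets [{resp.start}, {resp.end}) outside source of "
            f"length {len(source)} (key={req.key})",
            backend=backend.name,
        )
    if resp.end - resp.start > req.max_span_chars:
        raise ContractViolation(
            f"span length {resp.end - resp.start} exceeds cap "
            f"{req.max_span_chars} (key={req.key})",
            backend=backend.name,
        )
    if source[resp.start : resp.end] != resp.span:
        raise ContractViolation(
            f"span is not the verbatim slice source[{resp.start}:{resp.end}] "
            f"(key={req.key})",
            backend=backend.name,
        )
    return resp


# ---------------------------------------------------------------------------
# Scripted backend


class ScriptedBackend(Backend):
    """Fully deterministic backend driven by an explicit answer table.

    ``script`` maps request keys to a choice string (for choices) or an
    ``(start, end)`` pair / ``{"start": .., "end": ..}`` object (for
    spans). An unknown key is an explicit :class:`ScriptError` — there are
    no defaults, so a missing entry fails loudly at the node it concerns.

    Target-selection rounds arrive with round-suffixed keys
    (``target_select#0``, ``target_select#1``, ...), one entry per round.
    """

    name = "scripted"

    def __init__(self, script: Mapping[str, object]):
        self.script = dict(script)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "ScriptedBackend":
        with open(path, encoding="utf-8") as fh:
            return cls(json.load(fh))

    def _lookup(self, key: str):
        if key not in self.script:
            raise ScriptError(f"scripted backend has no entry for key {key!r}")
        return self.script[key]

    def _choose(self, req: ChoiceRequest) -> ChoiceResponse:
        entry = self._lookup(req.key)
        if isinstance(entry, dict) and "selected" in entry:
            selected = entry["selected"]
            reasoning = entry.get("reasoning", f"scripted answer for {req.key}")
        elif isinstance(entry, str):
            selected = entry
            reasoning = f"scripted answer for {req.key}"
        else:
            raise ScriptError(f"script entry for {req.key!r} is not a choice")
        return ChoiceResponse(
            selected=selected,
            reasoning=reasoning,
            reasoning_tokens_used=count_tokens(reasoning),
        )

    def _extract_span(self, req: SpanRequest) -> SpanResponse:
        entry = self._lookup(req.key + ":evidence" if (req.key + ":evidence") in self.script else req.key)
        if isinstance(entry, dict) and "span" in entry and "start" not in entry:
            # adversarial form used in negative tests: a free-text span
            text = str(entry["span"])
            start = int(entry.get("claim_start", 0))
            return SpanResponse(span=text, start=start, end=start + len(text))
        if isinstance(entry, dict):
            start, end = int(entry["start"]), int(entry["end"])
        elif isinstance(entry, (list, tuple)) and len(entry) == 2:
            start, end = int(entry[0]), int(entry[1])
        else:
            raise ScriptError(f"script entry for {req.key!r} is not a span")
        reasoning = f"scripted span for {req.key}"
        return SpanResponse(
            span=req.source[start:end], start=start, end=end, reasoning=reasoning
        )


# ---------------------------------------------------------------------------
# Keyword backend


@dataclass(frozen=True)
class KeywordRule:
    """One ordered rule: if ``pattern`` matches the prompt at a node in
    ``scope`` (None = any node), answer ``answer``. First match wins."""

    pattern: str
    scope: Optional[str]
    answer: str

    def compiled(self) -> re.Pattern:
        return re.compile(self.pattern)


_SENTENCE_SPLIT = re.compile(r"(?<=[.!?])\s+")

#: Canonical-label synonyms for the keyword backend's heading choice.
HEADING_SYNONYMS: Dict[str, Tuple[str, ...]] = {
    "abstract": ("abstract",),
    "introduction": ("introduction", "background"),
    "methods": ("method", "materials", "procedure", "experimental"),
    "results": ("result", "finding"),
    "discussion": ("discussion", "concluding", "conclusion"),
}


class KeywordBackend(Backend):
    """Regex-rule backend standing in for a reasoning model.

    Decision nodes are answered by the first matching rule (rule order is
    semantics), defaulting to ``default_answer``. Heading-normalization
    requests are answered from a synonym table; target-selection requests
    pick the first remaining gene symbol whose 3'UTR-fusion validation
    phrase occurs in the prompt, else ``DONE``. Span requests return the
    first sentence of the source matching a rule in scope.
    """

    name = "keyword"

    def __init__(
        self,
        rules: Sequence[KeywordRule],
        default_answer: str = "no",
        target_validation_patterns: Sequence[str] = (
            r"3'UTR of (?:the )?{symbol}\b",
        ),
        heading_synonyms: Mapping[str, Tuple[str, ...]] = None,
    ):
        self.rules = list(rules)
        self.default_answer = default_answer
        self.target_validation_patterns = list(target_validation_patterns)
        self.heading_synonyms = dict(heading_synonyms or HEADING_SYNONYMS)
        self._compiled = [(r, r.compiled()) for r in self.rules]

    @classmethod
    def from_file(cls, path: Union[str, Path], **kw) -> "KeywordBackend":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        rules = [
            KeywordRule(pattern=r["pattern"], scope=r.get("scope"), answer=r["answer"])
            for r in raw
        ]
        return cls(rules, **kw)

    # -- choices

    def _choose(self, req: ChoiceRequest) -> ChoiceResponse:
        if req.key.startswith(HEADING_KEY_PREFIX):
            return self._choose_heading(req)
        if req.key == TARGET_SELECT_KEY or req.key.startswith(TARGET_SELECT_KEY + "#"):
            return self._choose_target(req)
        # match against the article text only, not the node guidance
        context = req.prompt.rsplit(SECTION_DELIM, 1)[-1]
        for rule, pat in self._compiled:
            if rule.scope is not None and rule.scope != req.key:
                continue
            if pat.search(context):
                reasoning = (
                    f"rule {rule.pattern!r} matched at node {req.key}; "
                    f"answer {rule.answer}"
                )
                return ChoiceResponse(
                    selected=rule.answer,
                    reasoning=reasoning,
                    reasoning_tokens_used=count_tokens(reasoning),
                )
        reasoning = f"no rule matched at node {req.key}; default {self.default_answer}"
        return ChoiceResponse(
            selected=self.default_answer,
            reasoning=reasoning,
            reasoning_tokens_used=count_tokens(reasoning),
        )

    def _choose_heading(self, req: ChoiceRequest) -> ChoiceResponse:
        label = req.key[len(HEADING_KEY_PREFIX) :]
        needles = self.heading_synonyms.get(label, (label,))
        for option in req.options:
            if option == NONE_SENTINEL:
                continue
            low = option.lower()
            if any(n in low for n in needles):
                reasoning = f"heading {option!r} matches canonical {label!r}"
                return ChoiceResponse(
                    option, reasoning, count_tokens(reasoning)
                )
        reasoning = f"no heading matches canonical {label!r}"
        selected = NONE_SENTINEL if NONE_SENTINEL in req.options else req.options[0]
        return ChoiceResponse(selected, reasoning, count_tokens(reasoning))

    def _choose_target(self, req: ChoiceRequest) -> ChoiceResponse:
        for option in req.options:
            if option in (DONE_SENTINEL, NOT_IN_LIST_SENTINEL):
                continue
            for tmpl in self.target_validation_patterns:
                pat = tmpl.format(symbol=re.escape(option))
                if re.search(pat, req.prompt):
                    reasoning = f"validation phrase found for target {option}"
                    return ChoiceResponse(option, reasoning, count_tokens(reasoning))
        reasoning = "no further validated targets in context"
        selected = DONE_SENTINEL if DONE_SENTINEL in req.options else req.options[0]
        return ChoiceResponse(selected, reasoning, count_tokens(reasoning))

    # -- spans

    def _extract_span(self, req: SpanRequest) -> SpanResponse:
        sentences = self._sentences(req.source)
        for rule, pat in self._compiled:
            if rule.scope is not None and rule.scope != req.key:
                continue
            for start, end in sentences:
                if pat.search(req.source[start:end]):
                    start, end = self._fit(req.source, start, end, req.max_span_chars)
                    reasoning = f"first sentence matching rule {rule.pattern!r}"
                    return SpanResponse(
                        req.source[start:end], start, end, reasoning
                    )
        start, end = sentences[0]
        start, end = self._fit(req.source, start, end, req.max_span_chars)
        return SpanResponse(
            req.source[start:end], start, end, "no rule matched; first sentence"
        )

    @staticmethod
    def _sentences(text: str) -> List[Tuple[int, int]]:
        spans, pos = [], 0
        for m in _SENTENCE_SPLIT.finditer(text):
            if m.start() > pos:
                spans.append((pos, m.start()))
            pos = m.end()
        if pos < len(text):
            spans.append((pos, len(text)))
        return spans or [(0, len(text))]

    @staticmethod
    def _fit(source: str, start: int, end: int, cap: int) -> Tuple[int, int]:
        if end - start > cap:
            end = start + cap
        return start, end
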