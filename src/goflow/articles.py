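"""Sectioned article model over JATS / EuropePMC full-text XML.

The pipeline works on article *sections* rather than whole texts: each
flowchart node names the canonical section most likely to answer it, and
that section's text is loaded lazily, once, under a global context-token
budget. Because journals name sections freely ("MATERIALS AND METHODS",
"Findings", ...), canonical labels are resolved to actual headings by a
zero-shot constrained choice against the article's real headings — the
backend decides; the core applies no string-similarity heuristic.

Section text is normalized (Unicode NFC, runs of spaces/tabs collapsed,
paragraph breaks kept as single newlines) so that evidence-span character
offsets are stable across serialization.
"""

from __future__ import annotations

import gzip
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

from lxml import etree

from . import backends
from .backends import (
    Backend,
    ChoiceRequest,
    NONE_SENTINEL,
    count_tokens,
)
from .errors import ArticleParseError, BudgetExhausted

CANONICAL_LABELS = ("abstract", "introduction", "methods", "results", "discussion")


@dataclass
class Article:
    """A parsed full-text article: metadata plus ordered (heading, body)
    sections with normalized plain-text bodies."""

    pmcid: str
    pmid: Optional[str]
    title: str
    pub_types: set
    sections: List[Tuple[str, str]]
    abstract: str = ""
    retraction_linked: bool = False

    def headings(self) -> List[str]:
        return [h for h, _ in self.sections]

    def body_text(self) -> str:
        return "\n".join(body for _, body in self.sections)

    def full_text(self) -> str:
        return "\n".join(
            part for part in (self.title, self.abstract, self.body_text()) if part
        )


#: canonical label -> actual heading present in the article
SectionIndex = Dict[str, str]


@dataclass(frozen=True)
class ContextBudget:
    """Token budgets for one curation run.

    ``max_context_tokens`` caps all section text ever charged to the run
    (the context-window limit of the decoding model); the evidence cap
    bounds how much text is offered for substring extraction at a node.
    """

    max_context_tokens: int = 64000
    max_evidence_source_tokens: int = 4000

    def __post_init__(self):
        if self.max_context_tokens <= 0 or self.max_evidence_source_tokens <= 0:
            raise ValueError("budgets must be positive")
        if self.max_evidence_source_tokens > self.max_context_tokens:
            raise ValueError("evidence cap must not exceed the context cap")


@dataclass
class LoadEvent:
    label: str
    heading: Optional[str]
    tokens_charged: int
    fallback: bool
    truncated: bool


@dataclass
class SectionCache:
    """Per-run lazy section loader: charges the budget once per section
    and replays cached text for free afterwards."""

    budget: ContextBudget
    charged_tokens: int = 0
    loaded: Dict[str, str] = field(default_factory=dict)
    log: List[LoadEvent] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Parsing


def normalize_text(text: str) -> str:
    """NFC-normalize, collapse space/tab runs, keep newlines as paragraph
    breaks, strip blank lines."""
    text = unicodedata.normalize("NFC", text)
    lines = [re.sub(r"[ \t\r\f\v]+", " ", ln).strip() for ln in text.split("\n")]
    return "\n".join(ln for ln in lines if ln)


def parse_jats(xml: bytes) -> Article:
    """Parse JATS (or the EuropePMC full-text dialect) into an Article.

    Top-level ``<sec>`` elements of the body become sections in document
    order; nested ``<sec>`` text is folded into its top-level parent,
    depth-first. Publication types are collected from the ``article-type``
    attribute and ``<article-categories>`` subjects. Gzipped input is
    handled transparently.
    """
    if xml[:2] == b"\x1f\x8b":
        xml = gzip.decompress(xml)
    try:
        root = etree.fromstring(xml)
    except etree.XMLSyntaxError as exc:
        raise ArticleParseError(f"not well-formed XML: {exc}") from exc

    if root.tag != "article":
        found = root.find(".//article")
        if found is None:
            raise ArticleParseError("no <article> element")
        root = found

    pmcid = _article_id(root, "pmcid") or _article_id(root, "pmc") or ""
    if pmcid and not pmcid.startswith("PMC"):
        pmcid = "PMC" + pmcid
    pmid = _article_id(root, "pmid")

    body = root.find("body")
    if body is None:
        raise ArticleParseError("document has no <body>", pmcid=pmcid or None)

    pub_types = set()
    atype = root.get("article-type")
    if atype:
        pub_types.add(atype)
    for subj in root.iterfind(".//article-categories//subject"):
        if subj.text and subj.text.strip():
            pub_types.add(subj.text.strip())

    retraction_linked = any(
        rel.get("related-article-type", "").startswith("retract")
        for rel in root.iterfind(".//related-article")
    )

    title_el = root.find(".//title-group/article-title")
    title = normalize_text(_all_text(title_el)) if title_el is not None else ""

    abstract_el = root.find(".//front//abstract")
    abstract = normalize_text(_all_text(abstract_el)) if abstract_el is not None else ""

    sections: List[Tuple[str, str]] = []
    for sec in body.findall("sec"):
        title_node = sec.find("title")
        heading = _all_text(title_node).strip() if title_node is not None else ""
        body_parts = [
            _all_text(child)
            for child in sec
            if child is not title_node
        ]
        sections.append((heading, normalize_text("\n".join(body_parts))))
    if not sections:
        # bodies without <sec> structure: treat the whole body as one section
        sections.append(("", normalize_text(_all_text(body))))

    return Article(
        pmcid=pmcid,
        pmid=pmid,
        title=title,
        pub_types=pub_types,
        sections=sections,
        abstract=abstract,
        retraction_linked=retraction_linked,
    )


def parse_jats_file(path: Union[str, Path]) -> Article:
    return parse_jats(Path(path).read_bytes())


def _article_id(root, id_type: str) -> Optional[str]:
    for el in root.iterfind(".//front//article-id"):
        if el.get("pub-id-type") == id_type and el.text:
            return el.text.strip()
    return None


def _all_text(el) -> str:
    if el is None:
        return ""
    # depth-first text with paragraph/sec boundaries as newlines
    parts = []
    if el.text:
        parts.append(el.text)
    for child in el:
        parts.append(_all_text(child))
        if child.tag in ("p", "sec", "title"):
            parts.append("\n")
        if child.tail:
            parts.append(child.tail)
    return "".join(parts)


# ---------------------------------------------------------------------------
# Heading normalization


def normalize_headings(
    article: Article,
    backend: Backend,
    labels: Tuple[str, ...] = CANONICAL_LABELS,
) -> SectionIndex:
    """Map canonical section labels to the article's actual headings.

    For each canonical label in order, the backend answers a constrained
    choice among the article's not-yet-claimed headings plus a ``NONE``
    sentinel; ``NONE`` leaves the label out of the index. Already-claimed
    headings are withheld from later choices, so the mapping is injective
    by construction.
    """
    if not article.sections:
        raise ArticleParseError("article has no sections", pmcid=article.pmcid)
    index: SectionIndex = {}
    claimed = set()
    real_headings = [h for h in article.headings() if h]
    for label in labels:
        available = [h for h in real_headings if h not in claimed]
        if not available:
            break
        req = ChoiceRequest(
            key=backends.HEADING_KEY_PREFIX + label,
            prompt=(
                f"Select the article heading that corresponds to the standard "
                f"section {label!r}, or NONE if no heading matches.\n"
                "Headings: " + "; ".join(available)
            ),
            options=tuple(available) + (NONE_SENTINEL,),
        )
        resp = backends.choose(backend, req)
        if resp.selected != NONE_SENTINEL:
            index[label] = resp.selected
            claimed.add(resp.selected)
    return index


# ---------------------------------------------------------------------------
# Budgeted lazy loading


def get_section(
    article: Article,
    label: str,
    index: SectionIndex,
    cache: SectionCache,
    fallback: str = "abstract_then_body",
) -> str:
    """Return the text for a canonical section label, lazily and at most
    once charged against the run budget.

    When the label is unmapped, the configured fallback supplies text
    (default: abstract, then full body) and the load log flags it — an
    absent section is surfaced, never silently empty. Oversized sections
    are truncated to a prefix ending at a paragraph boundary.
    """
    if label in cache.loaded:
        return cache.loaded[label]

    text: Optional[str] = None
    heading: Optional[str] = None
    used_fallback = False
    if label in index:
        heading = index[label]
        for h, body in article.sections:
            if h == heading:
                text = body
                break
    elif label == "abstract" and article.abstract:
        text = article.abstract
        heading = "(abstract)"
    if text is None:
        used_fallback = True
        if fallback == "abstract_then_body":
            text = article.abstract or article.body_text()
            heading = None
        elif fallback == "body":
            text = article.body_text()
            heading = None
        else:
            raise BudgetExhausted(
                f"section {label!r} absent and fallback policy {fallback!r} unknown"
            )
        if not text:
            raise ArticleParseError(
                f"section {label!r} absent and no fallback text available",
                pmcid=article.pmcid,
            )

    remaining = cache.budget.max_context_tokens - cache.charged_tokens
    kept, truncated = _pack_paragraphs(text, remaining)
    if kept is None:
        raise BudgetExhausted(
            f"context budget exhausted loading section {label!r} "
            f"({cache.charged_tokens}/{cache.budget.max_context_tokens} tokens used)"
        )
    tokens = count_tokens(kept)
    cache.charged_tokens += tokens
    cache.loaded[label] = kept
    cache.log.append(
        LoadEvent(
            label=label,
            heading=heading,
            tokens_charged=tokens,
            fallback=used_fallback,
            truncated=truncated,
        )
    )
    return kept


def _pack_paragraphs(text: str, max_tokens: int) -> Tuple[Optional[str], bool]:
    """Greedy paragraph packing: the longest paragraph-aligned prefix that
    fits in *max_tokens*. Returns (None, True) when not even the first
    paragraph fits."""
    if count_tokens(text) <= max_tokens:
        return text, False
    kept: List[str] = []
    used = 0
    for para in text.split("\n"):
        t = count_tokens(para)
        if used + t > max_tokens:
            break
        kept.append(para)
        used += t
    if not kept:
        return None, True
    return "\n".join(kept), True
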