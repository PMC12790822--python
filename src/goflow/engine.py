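"""Per-article curation runs: traversal, evidence capture, annotation.

One run takes a pre-filtered article through the flowchart: each filter
or decision node is answered by a constrained yes/no choice over an
assembled prompt (the node's curation-manual prompt plus the lazily
loaded hinted section); decision nodes additionally capture a verbatim
evidence span with byte-exact offsets. A terminal payload plus resolved
targets becomes one annotation per (GO term x target) pair; dispositions
end the run as ``filtered`` or ``no_annotation``. Every visited node
yields exactly one :class:`NodeDecision`, in order, together with the
backend's verbatim reasoning trace — the auditable curation record that
human reviewers see.

Records are fully replayable: :func:`record_to_script` turns a record's
decisions into a scripted backend that reproduces the identical record
(modulo timestamp), the determinism contract behind curator review.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

from . import backends as _bk
from . import flowchart as _fc
from .articles import (
    Article,
    ContextBudget,
    SectionCache,
    SectionIndex,
    get_section,
    normalize_headings,
)
from .backends import (
    Backend,
    ChoiceRequest,
    ScriptedBackend,
    SpanRequest,
    choose,
    extract_span,
)
from .corpus import MirnaMention, detect_mirna_ids, distinct_mirnas, resolve_urs
from .errors import (
    BudgetExhausted,
    ContractViolation,
    IntegrityError,
    SpecificityError,
)
from .flowchart import (
    Aspect,
    Disposition,
    FlowNode,
    Flowchart,
    NodeKind,
    successor,
)
from .targets import (
    GeneMentionList,
    TargetSet,
    resolve_target_set,
    select_targets,
)

STATUS_ANNOTATED = "annotated"
STATUS_FILTERED = "filtered"
STATUS_NO_ANNOTATION = "no_annotation"
STATUS_ERROR = "error"

#: Default relation ids: BP -> involved_in, MF -> enables.
DEFAULT_RELATIONS = {"BP": "RO:0002331", "MF": "RO:0002327"}
#: Annotation-extension relation carrying the target ("has input" style).
DEFAULT_EXTENSION_RELATION = "RO:0002233"
#: Evidence code for unreviewed machine-produced candidate annotations.
DEFAULT_ECO = "ECO:0000203"


@dataclass(frozen=True)
class EngineConfig:
    budget: ContextBudget = field(default_factory=ContextBudget)
    max_targets: int = 4
    max_span_chars: int = 600
    evidence_at_decisions: bool = True
    fallback: str = "abstract_then_body"
    target_context_label: str = "results"
    relations: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_RELATIONS)
    )
    extension_relation: str = DEFAULT_EXTENSION_RELATION
    evidence_code: str = DEFAULT_ECO
    assigned_by: str = "goflow"

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode("utf-8")).hexdigest()[:12]


@dataclass
class Evidence:
    section: str
    start: int
    end: int
    span: str


@dataclass
class NodeDecision:
    node_id: str
    answer: str
    reasoning: str
    prompt_used: str
    evidence: Optional[Evidence] = None
    evidence_error: Optional[str] = None
    reasoning_tokens_used: int = 0


@dataclass
class Annotation:
    subject_urs_taxid: Optional[str]
    go_term: str
    aspect: str
    relation: str
    target_symbol: str
    target_accession: Optional[str]
    reference: Optional[str]
    evidence_code: str
    assigned_by: str


@dataclass
class CurationRecord:
    pmcid: str
    pmid: Optional[str]
    mirna: Optional[MirnaMention]
    decisions: List[NodeDecision]
    status: str
    annotations: List[Annotation] = field(default_factory=list)
    outcome_terms: List[Tuple[str, str]] = field(default_factory=list)
    terminal_id: Optional[str] = None
    failure_note: Optional[str] = None
    section_index: SectionIndex = field(default_factory=dict)
    load_log: List[dict] = field(default_factory=list)
    targets_rejected: List[Tuple[str, str]] = field(default_factory=list)
    target_rounds: List[str] = field(default_factory=list)
    run_metadata: Dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        # tuples -> lists for stable JSON round-trips
        return json.loads(json.dumps(d))

    @classmethod
    def from_dict(cls, d: dict) -> "CurationRecord":
        mirna = MirnaMention(**d["mirna"]) if d.get("mirna") else None
        decisions = []
        for dd in d["decisions"]:
            ev = Evidence(**dd["evidence"]) if dd.get("evidence") else None
            decisions.append(
                NodeDecision(
                    node_id=dd["node_id"],
                    answer=dd["answer"],
                    reasoning=dd["reasoning"],
                    prompt_used=dd["prompt_used"],
                    evidence=ev,
                    evidence_error=dd.get("evidence_error"),
                    reasoning_tokens_used=dd.get("reasoning_tokens_used", 0),
                )
            )
        anns = [Annotation(**a) for a in d.get("annotations", [])]
        return cls(
            pmcid=d["pmcid"],
            pmid=d.get("pmid"),
            mirna=mirna,
            decisions=decisions,
            status=d["status"],
            annotations=anns,
            outcome_terms=[tuple(t) for t in d.get("outcome_terms", [])],
            terminal_id=d.get("terminal_id"),
            failure_note=d.get("failure_note"),
            section_index=d.get("section_index", {}),
            load_log=d.get("load_log", []),
            targets_rejected=[tuple(t) for t in d.get("targets_rejected", [])],
            target_rounds=d.get("target_rounds", []),
            run_metadata=d.get("run_metadata", {}),
        )

    def answer_vector(self) -> _fc.AnswerVector:
        return {d.node_id: d.answer for d in self.decisions}


# ---------------------------------------------------------------------------
# Prompt assembly


def assemble_prompt(
    node: FlowNode,
    article: Article,
    index: SectionIndex,
    cache: SectionCache,
    config: Optional[EngineConfig] = None,
) -> str:
    """Node prompt plus the delimited text of its hinted section.

    Section text comes through the lazy budgeted cache, so assembling two
    prompts against the same section charges the budget once and yields
    identical text both times.
    """
    config = config or EngineConfig()
    label = node.section_hint or "results"
    try:
        text = get_section(article, label, index, cache, fallback=config.fallback)
    except BudgetExhausted as exc:
        raise BudgetExhausted(f"at node {node.node_id!r}: {exc}") from exc
    return (
        f"{node.prompt}\n\n{_bk.SECTION_DELIM} {label} ---\n{text}\n--- end section ---"
    )


# ---------------------------------------------------------------------------
# Evidence capture


def attach_evidence(
    decision: NodeDecision,
    node: FlowNode,
    article: Article,
    index: SectionIndex,
    backend: Backend,
    cache: SectionCache,
    config: EngineConfig,
) -> NodeDecision:
    """Capture a verbatim evidence span for an answered decision node.

    Evidence is best-effort: a backend contract violation leaves the
    answer intact and marks the evidence absent with the reason. Offsets
    are 0-based half-open into the cached section text.
    """
    label = node.section_hint or "results"
    source = get_section(article, label, index, cache, fallback=config.fallback)
    req = SpanRequest(
        key=node.node_id,
        prompt=(
            f"Quote the passage that best supports the answer "
            f"{decision.answer!r} to: {node.question}"
        ),
        source=source,
        max_source_tokens=config.budget.max_evidence_source_tokens,
        max_span_chars=config.max_span_chars,
    )
    try:
        resp = extract_span(backend, req)
    except ContractViolation as exc:
        decision.evidence = None
        decision.evidence_error = str(exc)
        return decision
    decision.evidence = Evidence(
        section=label, start=resp.start, end=resp.end, span=resp.span
    )
    return decision


# ---------------------------------------------------------------------------
# The run


def run_flowchart(
    article: Article,
    fc: Flowchart,
    backend: Backend,
    config: Optional[EngineConfig] = None,
    *,
    mirna: Optional[MirnaMention] = None,
    gene_mentions: Optional[GeneMentionList] = None,
    urs_lookup: Optional[Mapping[str, str]] = None,
    uniprot_lookup: Optional[Mapping[Tuple[str, int], str]] = None,
    section_index: Optional[SectionIndex] = None,
    timestamp: Optional[str] = None,
) -> CurationRecord:
    """Run one article through the flowchart and assemble its record.

    The article is assumed to have passed corpus filtering. When *mirna*
    is not supplied it is detected from the article text (the single
    distinct identifier the filter guarantees). Backend contract
    violations and budget exhaustion end the run with ``status="error"``
    and the cause in ``failure_note`` — partial decisions are kept.
    """
    config = config or EngineConfig()
    cache = SectionCache(budget=config.budget)
    record = CurationRecord(
        pmcid=article.pmcid,
        pmid=article.pmid,
        mirna=mirna,
        decisions=[],
        status=STATUS_ERROR,
        run_metadata={
            "flowchart": f"{fc.name}@{fc.version}",
            "backend": backend.name,
            "config_hash": config.hash(),
            "timestamp": timestamp or _dt.datetime.now(_dt.timezone.utc).isoformat(),
        },
    )

    if record.mirna is None:
        ids = detect_mirna_ids(article.full_text())
        names = distinct_mirnas(ids)
        if len(names) == 1:
            record.mirna = next(m for m in ids if m.normalized_id == names[0])
    if record.mirna is not None and urs_lookup is not None:
        record.mirna = resolve_urs(record.mirna, urs_lookup)

    try:
        index = (
            dict(section_index)
            if section_index is not None
            else normalize_headings(article, backend)
        )
        record.section_index = index

        cur = fc.root
        terminal: Optional[FlowNode] = None
        while True:
            node = fc.node(cur)
            if node.kind is NodeKind.TERMINAL:
                terminal = node
                break
            prompt = assemble_prompt(node, article, index, cache, config)
            resp = choose(
                backend,
                ChoiceRequest(key=node.node_id, prompt=prompt, options=("yes", "no")),
            )
            decision = NodeDecision(
                node_id=node.node_id,
                answer=resp.selected,
                reasoning=resp.reasoning,
                prompt_used=prompt,
                reasoning_tokens_used=resp.reasoning_tokens_used,
            )
            if node.kind is NodeKind.DECISION and config.evidence_at_decisions:
                attach_evidence(decision, node, article, index, backend, cache, config)
            record.decisions.append(decision)

            nxt = successor(fc, cur, resp.selected)
            if isinstance(nxt, Disposition):
                record.status = nxt.value
                record.load_log = [asdict(e) for e in cache.log]
                return record
            cur = nxt
    except (ContractViolation, BudgetExhausted) as exc:
        record.status = STATUS_ERROR
        record.failure_note = str(exc)
        record.load_log = [asdict(e) for e in cache.log]
        return record

    record.terminal_id = terminal.node_id
    record.outcome_terms = [(p.term, p.aspect.value) for p in terminal.payload]

    if gene_mentions is None:
        record.status = STATUS_NO_ANNOTATION
        record.failure_note = "no gene mention list available; no validated target"
        record.load_log = [asdict(e) for e in cache.log]
        return record

    try:
        context = get_section(
            article, config.target_context_label, index, cache, fallback=config.fallback
        )
        ts = select_targets(context, gene_mentions, backend, config.max_targets)
    except (ContractViolation, BudgetExhausted) as exc:
        record.status = STATUS_ERROR
        record.failure_note = str(exc)
        record.load_log = [asdict(e) for e in cache.log]
        return record
    if uniprot_lookup is not None and record.mirna is not None:
        resolve_target_set(ts, uniprot_lookup, record.mirna.taxon)

    record.target_rounds = list(ts.rounds)
    record.load_log = [asdict(e) for e in cache.log]
    return finalize_annotations(record, ts, fc, config)


# ---------------------------------------------------------------------------
# Finalization


def finalize_annotations(
    record: CurationRecord,
    target_set: TargetSet,
    fc: Flowchart,
    config: Optional[EngineConfig] = None,
) -> CurationRecord:
    """Turn a terminal outcome plus resolved targets into annotations.

    Emits one annotation per (payload term x validated target). Zero
    validated targets downgrades the record to ``no_annotation`` (GO
    annotations of this type are target-anchored) while preserving the
    full trace. Before emission the recorded answers are replayed through
    the flowchart: a record carrying the bare parent term while its
    answers replay to a child-term terminal is a specificity violation
    and raises; any other replay mismatch raises an integrity error.
    """
    config = config or EngineConfig()
    if record.terminal_id is None or not record.outcome_terms:
        raise IntegrityError("finalize called on a record with no terminal outcome")

    _check_replay_consistency(record, fc)

    record.targets_rejected = list(target_set.rejected)
    if target_set.unresolvable or not target_set.validated:
        record.status = STATUS_NO_ANNOTATION
        record.failure_note = target_set.note or "no validated target"
        record.annotations = []
        return record

    subject = record.mirna.urs_taxid if record.mirna else None
    anns: List[Annotation] = []
    for term, aspect in record.outcome_terms:
        for symbol, accession in target_set.validated:
            anns.append(
                Annotation(
                    subject_urs_taxid=subject,
                    go_term=term,
                    aspect=aspect,
                    relation=config.relations.get(aspect, ""),
                    target_symbol=symbol,
                    target_accession=accession,
                    reference=f"PMID:{record.pmid}" if record.pmid else None,
                    evidence_code=config.evidence_code,
                    assigned_by=config.assigned_by,
                )
            )
    record.annotations = anns
    record.status = STATUS_ANNOTATED
    return record


def _check_replay_consistency(record: CurationRecord, fc: Flowchart) -> None:
    outcome = _fc.replay(fc, record.answer_vector())
    if isinstance(outcome, Disposition):
        raise IntegrityError(
            f"record {record.pmcid}: answers replay to disposition "
            f"{outcome.value!r}, not a terminal"
        )
    replay_bp = {p.term for p in outcome if p.aspect is Aspect.BP}
    recorded_bp = {t for t, a in record.outcome_terms if a == "BP"}
    if replay_bp == recorded_bp:
        return
    parents = set(fc.term_hierarchy.values())
    if recorded_bp <= parents and any(
        fc.term_hierarchy.get(child) in recorded_bp for child in replay_bp
    ):
        raise SpecificityError(
            f"record {record.pmcid}: recorded bare parent term(s) "
            f"{sorted(recorded_bp)} but answers replay to more specific "
            f"{sorted(replay_bp)}"
        )
    raise IntegrityError(
        f"record {record.pmcid}: recorded outcome {sorted(recorded_bp)} does "
        f"not match replayed outcome {sorted(replay_bp)}"
    )


# ---------------------------------------------------------------------------
# Replay


def record_to_script(record: CurationRecord, target_order: Optional[List[str]] = None) -> dict:
    """Build a scripted-backend script reproducing this record's run.

    Includes heading choices (from the stored section index), per-node
    answers with their original reasoning, evidence offsets, and the
    target-selection rounds (validated symbols in order, then DONE).
    """
    from .articles import CANONICAL_LABELS

    script: dict = {}
    for label in CANONICAL_LABELS:
        key = _bk.HEADING_KEY_PREFIX + label
        script[key] = record.section_index.get(label, _bk.NONE_SENTINEL)
    for d in record.decisions:
        script[d.node_id] = {"selected": d.answer, "reasoning": d.reasoning}
        if d.evidence is not None:
            script[d.node_id + ":evidence"] = {
                "start": d.evidence.start,
                "end": d.evidence.end,
            }
    rounds = list(record.target_rounds) if target_order is None else (
        list(target_order) + [_bk.DONE_SENTINEL]
    )
    if not rounds and record.annotations:
        rounds = list(
            dict.fromkeys(a.target_symbol for a in record.annotations)
        ) + [_bk.DONE_SENTINEL]
    for i, sel in enumerate(rounds):
        script[f"{_bk.TARGET_SELECT_KEY}#{i}"] = sel
    return script


def replay_record(
    record: CurationRecord,
    article: Article,
    fc: Flowchart,
    config: Optional[EngineConfig] = None,
    *,
    gene_mentions: Optional[GeneMentionList] = None,
    urs_lookup: Optional[Mapping[str, str]] = None,
    uniprot_lookup: Optional[Mapping[Tuple[str, int], str]] = None,
) -> CurationRecord:
    """Re-run an article with the record's decisions as a scripted
    backend. With the same inputs the result is identical to the original
    record, timestamp aside."""
    script = record_to_script(record)
    backend = ScriptedBackend(script)
    backend.name = record.run_metadata.get("backend", "scripted")
    base = MirnaMention(
        raw_text=record.mirna.raw_text,
        scheme=record.mirna.scheme,
        organism_prefix=record.mirna.organism_prefix,
        normalized_id=record.mirna.normalized_id,
    ) if record.mirna else None
    return run_flowchart(
        article,
        fc,
        backend,
        config,
        mirna=base,
        gene_mentions=gene_mentions,
        urs_lookup=urs_lookup,
        uniprot_lookup=uniprot_lookup,
        timestamp=record.run_metadata.get("timestamp"),
    )


def records_equal_modulo_timestamp(a: CurationRecord, b: CurationRecord) -> bool:
    da, db = a.to_dict(), b.to_dict()
    da.get("run_metadata", {}).pop("timestamp", None)
    db.get("run_metadata", {}).pop("timestamp", None)
    return da == db


# ---------------------------------------------------------------------------
# Evidence revalidation


def revalidate_evidence(
    record: CurationRecord,
    article: Article,
    fc: Flowchart,
    config: Optional[EngineConfig] = None,
) -> List[str]:
    """Re-derive each decision's section text and check every stored span
    is the exact half-open slice it claims. Returns a list of problems
    (empty means all spans re-validate)."""
    config = config or EngineConfig()
    cache = SectionCache(budget=config.budget)
    problems: List[str] = []
    for d in record.decisions:
        if d.evidence is None:
            continue
        try:
            text = get_section(
                article, d.evidence.section, record.section_index, cache,
                fallback=config.fallback,
            )
        except Exception as exc:  # surface, never mask
            problems.append(f"{d.node_id}: cannot reload section: {exc}")
            continue
        sl = text[d.evidence.start : d.evidence.end]
        if sl != d.evidence.span:
            problems.append(
                f"{d.node_id}: span mismatch at [{d.evidence.start}, {d.evidence.end})"
            )
    return problems
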