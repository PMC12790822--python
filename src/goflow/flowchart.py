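"""Curation flowcharts: typed decision DAGs with per-node prompts.

A flowchart encodes expert curation guidance as a rooted binary decision
structure. Interior nodes are either cheap *filter* nodes (triage before
the real decision tree) or *decision* nodes (evidence-bearing yes/no
questions); leaves are *terminal* nodes carrying the GO terms to annotate.
A missing yes/no branch must declare an ``on_fail`` disposition —
``filtered`` for triage dead-ends, ``no_annotation`` for articles that
enter the tree but do not meet the evidence bar.

The machine-readable schema is fixed by this module (and mirrored in
``data/flowchart.schema.json``); the bundled miRNA gene-silencing fixture
in ``data/mirna_flowchart.json`` is a reconstruction of the GO
consortium's published curation guidance for GO:0035195 and its two
mechanism-specific child terms.
"""

from __future__ import annotations

import enum
import json
import re
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

from pydantic import BaseModel, Field, ValidationError, model_validator

from .errors import FlowchartLoadError, FlowchartUsageError

GO_ID_RE = re.compile(r"^GO:\d{7}$")

DATA_DIR = Path(__file__).parent / "data"
BUNDLED_FLOWCHART = DATA_DIR / "mirna_flowchart.json"
BUNDLED_PROMPTS = DATA_DIR / "mirna_prompts.json"

YES = "yes"
NO = "no"

#: Ordered yes/no answers keyed by node id along one root-to-outcome path.
AnswerVector = Dict[str, str]


class NodeKind(str, enum.Enum):
    FILTER = "filter"
    DECISION = "decision"
    TERMINAL = "terminal"


class Aspect(str, enum.Enum):
    BP = "BP"
    MF = "MF"


class Disposition(str, enum.Enum):
    """Where an article goes when it falls off the flowchart."""

    FILTERED = "filtered"
    NO_ANNOTATION = "no_annotation"


class PayloadTerm(BaseModel):
    """One GO term attached to a terminal node."""

    model_config = {"frozen": True}

    term: str
    aspect: Aspect

    @model_validator(mode="after")
    def _check_go_id(self):
        if not GO_ID_RE.match(self.term):
            raise ValueError(f"not a GO id: {self.term!r}")
        return self


#: A terminal outcome: the tuple of GO terms a reached terminal assigns.
Payload = Tuple[PayloadTerm, ...]
#: What a complete traversal yields.
Outcome = Union[Disposition, Payload]


class FlowNode(BaseModel):
    node_id: str
    kind: NodeKind
    question: str
    prompt: str = ""
    section_hint: Optional[str] = None
    yes_next: Optional[str] = None
    no_next: Optional[str] = None
    on_fail: Optional[Disposition] = None
    payload: List[PayloadTerm] = Field(default_factory=list)

    @property
    def payload_tuple(self) -> Payload:
        return tuple(self.payload)

    def branch(self, answer: str) -> Union[str, Disposition]:
        """Successor node id for *answer*, or the on_fail disposition."""
        if answer not in (YES, NO):
            raise FlowchartUsageError(f"answer must be yes/no, got {answer!r}")
        nxt = self.yes_next if answer == YES else self.no_next
        if nxt is not None:
            return nxt
        if self.on_fail is not None:
            return self.on_fail
        raise FlowchartUsageError(
            f"node {self.node_id!r} has no {answer!r} branch and no on_fail"
        )


class Flowchart(BaseModel):
    name: str
    version: str
    root: str
    nodes: Dict[str, FlowNode]
    term_hierarchy: Dict[str, str] = Field(default_factory=dict)

    def node(self, node_id: str) -> FlowNode:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise FlowchartUsageError(f"unknown node id {node_id!r}") from None

    def terminals(self) -> List[FlowNode]:
        return [n for n in self.nodes.values() if n.kind is NodeKind.TERMINAL]


# ---------------------------------------------------------------------------
# Loading


def load_flowchart(
    flowchart_json: Union[str, Path], prompts_json: Union[str, Path]
) -> Flowchart:
    """Load a flowchart JSON plus its companion per-node prompts file.

    Every filter/decision node must have a prompt entry; terminals may
    omit one. The returned flowchart has passed :func:`validate_flowchart`.
    """
    fc_raw = _read_json(flowchart_json)
    prompts = _read_json(prompts_json)
    if not isinstance(prompts, dict):
        raise FlowchartLoadError("prompts file must be a JSON object")

    nodes_raw = fc_raw.get("nodes")
    if not isinstance(nodes_raw, dict):
        raise FlowchartLoadError("flowchart JSON missing /nodes object")
    try:
        nodes = {}
        for node_id, spec in nodes_raw.items():
            nodes[node_id] = FlowNode(node_id=node_id, **spec)
        fc = Flowchart(
            name=fc_raw.get("name", "unnamed"),
            version=str(fc_raw.get("version", "0")),
            root=fc_raw["root"],
            nodes=nodes,
            term_hierarchy=fc_raw.get("term_hierarchy", {}),
        )
    except KeyError as exc:
        raise FlowchartLoadError(f"flowchart JSON missing /{exc.args[0]}") from exc
    except ValidationError as exc:
        first = exc.errors()[0]
        pointer = "/" + "/".join(str(p) for p in first["loc"])
        raise FlowchartLoadError(f"schema violation at {pointer}: {first['msg']}") from exc

    for node in fc.nodes.values():
        if node.kind is not NodeKind.TERMINAL and node.node_id not in prompts:
            raise FlowchartLoadError(f"missing prompt for node {node.node_id!r}")
        node.prompt = prompts.get(node.node_id, node.question)

    violations = validate_flowchart(fc)
    if violations:
        raise FlowchartLoadError("invalid flowchart: " + "; ".join(violations))
    return fc


def load_bundled_flowchart() -> Flowchart:
    """The miRNA gene-silencing flowchart shipped with the package."""
    return load_flowchart(BUNDLED_FLOWCHART, BUNDLED_PROMPTS)


def _read_json(path: Union[str, Path]):
    try:
        with open(path, encoding="utf-8") as fh:
            return json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise FlowchartLoadError(f"cannot read JSON from {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Validation


def validate_flowchart(fc: Flowchart) -> List[str]:
    """Return a list of invariant violations (empty means valid).

    Checks: root exists; every edge resolves; terminals have payload and
    no out-edges; filter/decision nodes cover both branches (edge or
    on_fail); no directed cycle; all nodes reachable from the root; at
    least one terminal reachable; hierarchy terms occur in some payload
    or as a common parent.
    """
    out: List[str] = []
    if fc.root not in fc.nodes:
        out.append(f"root {fc.root!r} is not a defined node")

    payload_terms = set()
    for node in fc.nodes.values():
        for target, label in ((node.yes_next, "yes_next"), (node.no_next, "no_next")):
            if target is not None and target not in fc.nodes:
                out.append(f"node {node.node_id!r}: dangling {label} -> {target!r}")
        if node.kind is NodeKind.TERMINAL:
            if not node.payload:
                out.append(f"terminal {node.node_id!r} has empty payload")
            if node.yes_next or node.no_next:
                out.append(f"terminal {node.node_id!r} has out-edge")
            payload_terms.update(p.term for p in node.payload)
        else:
            for target, label in ((node.yes_next, YES), (node.no_next, NO)):
                if target is None and node.on_fail is None:
                    out.append(
                        f"node {node.node_id!r}: {label} branch has no edge and no on_fail"
                    )
            if node.yes_next is None and node.no_next is None:
                out.append(f"node {node.node_id!r} has no out-edges at all")

    for child, parent in fc.term_hierarchy.items():
        known = payload_terms | set(fc.term_hierarchy.values())
        if child not in payload_terms:
            out.append(f"hierarchy child {child} not in any terminal payload")
        if parent not in known:
            out.append(f"hierarchy parent {parent} unknown")

    if fc.root in fc.nodes:
        reachable, cyclic = _walk(fc)
        if cyclic:
            out.append("directed cycle reachable from root")
        unreachable = set(fc.nodes) - reachable
        for node_id in sorted(unreachable):
            out.append(f"node {node_id!r} unreachable from root")
        if not any(
            fc.nodes[n].kind is NodeKind.TERMINAL for n in reachable
        ) and not cyclic:
            out.append("no terminal reachable from root")
    return out


def _walk(fc: Flowchart) -> Tuple[set, bool]:
    """Reachable node ids and whether a cycle is reachable (iterative DFS)."""
    WHITE, GREY, BLACK = 0, 1, 2
    color = {nid: WHITE for nid in fc.nodes}
    cyclic = False
    stack: List[Tuple[str, bool]] = [(fc.root, False)]
    while stack:
        nid, done = stack.pop()
        if done:
            color[nid] = BLACK
            continue
        if color[nid] == GREY:
            continue
        if color[nid] == BLACK:
            continue
        color[nid] = GREY
        stack.append((nid, True))
        node = fc.nodes[nid]
        for nxt in (node.yes_next, node.no_next):
            if nxt is None or nxt not in fc.nodes:
                continue
            if color[nxt] == GREY:
                cyclic = True
            elif color[nxt] == WHITE:
                stack.append((nxt, False))
    reachable = {nid for nid, c in color.items() if c != WHITE}
    return reachable, cyclic


# ---------------------------------------------------------------------------
# Traversal


def step(fc: Flowchart, node_id: str, answer: str) -> Union[str, Disposition, Payload]:
    """Advance one node: next node id, a disposition, or a terminal payload.

    Stepping on a terminal is a usage error; a missing branch returns the
    node's declared ``on_fail`` disposition verbatim.
    """
    node = fc.node(node_id)
    if node.kind is NodeKind.TERMINAL:
        raise FlowchartUsageError(f"cannot step on terminal node {node_id!r}")
    succ = node.branch(answer)
    if isinstance(succ, Disposition):
        return succ
    nxt = fc.node(succ)
    if nxt.kind is NodeKind.TERMINAL:
        return nxt.payload_tuple
    return succ


def successor(fc: Flowchart, node_id: str, answer: str) -> Union[str, Disposition]:
    """Like :func:`step` but returns the successor *node id* even for
    terminals (the curation engine needs the terminal's identity)."""
    node = fc.node(node_id)
    if node.kind is NodeKind.TERMINAL:
        raise FlowchartUsageError(f"cannot step on terminal node {node_id!r}")
    return node.branch(answer)


def replay(fc: Flowchart, answers: AnswerVector) -> Outcome:
    """Run a complete answer vector from the root to its outcome."""
    cur = fc.root
    if fc.node(cur).kind is NodeKind.TERMINAL:
        if answers:
            raise FlowchartUsageError("non-empty answer vector for terminal root")
        return fc.node(cur).payload_tuple
    for node_id, answer in answers.items():
        if node_id != cur:
            raise FlowchartUsageError(
                f"answer vector not contiguous: expected {cur!r}, got {node_id!r}"
            )
        res = successor(fc, cur, answer)
        if isinstance(res, Disposition):
            return res
        nxt = fc.node(res)
        if nxt.kind is NodeKind.TERMINAL:
            return nxt.payload_tuple
        cur = res
    raise FlowchartUsageError("answer vector ended before reaching an outcome")


def enumerate_paths(fc: Flowchart) -> List[Tuple[AnswerVector, Outcome]]:
    """Exhaustively unroll every root-to-outcome path.

    Returns one (answer vector, outcome) pair per leaf of the unrolled
    decision tree; serves as the brute-force oracle for :func:`step`.
    A flowchart whose root is a terminal yields one path with an empty
    answer vector.
    """
    violations = validate_flowchart(fc)
    if violations:
        raise FlowchartUsageError("flowchart invalid: " + "; ".join(violations))

    results: List[Tuple[AnswerVector, Outcome]] = []
    root = fc.node(fc.root)
    if root.kind is NodeKind.TERMINAL:
        return [({}, root.payload_tuple)]

    stack: List[Tuple[str, List[Tuple[str, str]]]] = [(fc.root, [])]
    while stack:
        nid, prefix = stack.pop()
        node = fc.node(nid)
        for answer in (NO, YES):  # pushed no-first so yes pops first
            vec = prefix + [(nid, answer)]
            res = node.branch(answer)
            if isinstance(res, Disposition):
                results.append((dict(vec), res))
                continue
            nxt = fc.node(res)
            if nxt.kind is NodeKind.TERMINAL:
                results.append((dict(vec), nxt.payload_tuple))
            else:
                stack.append((res, vec))
    return results
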