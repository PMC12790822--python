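"""Flowchart model: loading, validation, and traversal vs brute force."""

import copy
import json
import random

import pytest

from goflow.errors import FlowchartLoadError, FlowchartUsageError
from goflow.flowchart import (
    BUNDLED_FLOWCHART,
    BUNDLED_PROMPTS,
    Disposition,
    Flowchart,
    FlowNode,
    NodeKind,
    PayloadTerm,
    enumerate_paths,
    load_flowchart,
    replay,
    step,
    validate_flowchart,
)
from goflow.synth import random_flowchart


# ---------------------------------------------------------------------------
# Independent oracle: a recursively coded path enumerator


def recursive_paths(fc, node_id=None, prefix=()):
    node = fc.nodes[node_id or fc.root]
    if node.kind is NodeKind.TERMINAL:
        return [(dict(prefix), node.payload_tuple)]
    out = []
    for ans, edge in (("yes", node.yes_next), ("no", node.no_next)):
        vec = prefix + ((node.node_id, ans),)
        if edge is None:
            out.append((dict(vec), node.on_fail))
        elif fc.nodes[edge].kind is NodeKind.TERMINAL:
            out.append((dict(vec), fc.nodes[edge].payload_tuple))
        else:
            out.extend(recursive_paths(fc, edge, vec))
    return out


def as_set(paths):
    return {(tuple(vec.items()), outcome) for vec, outcome in paths}


# ---------------------------------------------------------------------------
# Bundled fixture structure


def test_bundled_fixture_bp_terms(fc):
    """The silencing flowchart curates the general term plus its two
    mechanism-specific children, and the MF co-term on every terminal."""
    bp = {
        p.term
        for t in fc.terminals()
        for p in t.payload
        if p.aspect.value == "BP"
    }
    assert bp == {"GO:0035195", "GO:0035278", "GO:0035279"}
    for t in fc.terminals():
        assert ("GO:1903231", "MF") in [(p.term, p.aspect.value) for p in t.payload]


def test_bundled_fixture_has_two_prefilters(fc):
    filters = [n for n in fc.nodes.values() if n.kind is NodeKind.FILTER]
    assert len(filters) == 2
    assert fc.node(fc.root).kind is NodeKind.FILTER


def test_bundled_fixture_is_valid(fc):
    assert validate_flowchart(fc) == []


def test_term_hierarchy_is_a_links(fc):
    assert fc.term_hierarchy == {
        "GO:0035278": "GO:0035195",
        "GO:0035279": "GO:0035195",
    }


def test_destabilization_path_exists(fc):
    outcomes = [
        {(p.term, p.aspect.value) for p in out}
        for _, out in enumerate_paths(fc)
        if not isinstance(out, Disposition)
    ]
    assert {("GO:0035279", "BP"), ("GO:1903231", "MF")} in outcomes


def test_specificity_encoded_structurally(fc):
    """No path reaching a child term passes through a parent-only
    terminal: terminals are leaves and each path carries one BP term."""
    for vec, out in enumerate_paths(fc):
        if isinstance(out, Disposition):
            continue
        bp = {p.term for p in out if p.aspect.value == "BP"}
        assert len(bp) == 1  # exactly one BP term per outcome


# ---------------------------------------------------------------------------
# Loading failures


def test_missing_prompt_names_node(tmp_path):
    with open(BUNDLED_FLOWCHART, encoding="utf-8") as fh:
        fc_raw = json.load(fh)
    with open(BUNDLED_PROMPTS, encoding="utf-8") as fh:
        prompts = json.load(fh)
    del prompts["mrna_level"]
    p1 = tmp_path / "fc.json"
    p2 = tmp_path / "prompts.json"
    p1.write_text(json.dumps(fc_raw))
    p2.write_text(json.dumps(prompts))
    with pytest.raises(FlowchartLoadError, match="mrna_level"):
        load_flowchart(p1, p2)


def test_schema_violation_reports_pointer(tmp_path):
    with open(BUNDLED_FLOWCHART, encoding="utf-8") as fh:
        fc_raw = json.load(fh)
    fc_raw["nodes"]["t_general"]["payload"][0]["term"] = "GO:35195"  # bad id
    p1 = tmp_path / "fc.json"
    p1.write_text(json.dumps(fc_raw))
    with pytest.raises(FlowchartLoadError, match="schema violation at /"):
        load_flowchart(p1, BUNDLED_PROMPTS)


def test_single_terminal_flowchart(tmp_path):
    p1 = tmp_path / "fc.json"
    p1.write_text(
        json.dumps(
            {
                "name": "one",
                "version": "1",
                "root": "t",
                "nodes": {
                    "t": {
                        "kind": "terminal",
                        "question": "t",
                        "payload": [{"term": "GO:0035195", "aspect": "BP"}],
                    }
                },
            }
        )
    )
    p2 = tmp_path / "prompts.json"
    p2.write_text("{}")
    fc = load_flowchart(p1, p2)
    paths = enumerate_paths(fc)
    assert paths == [({}, fc.node("t").payload_tuple)]
    assert replay(fc, {}) == fc.node("t").payload_tuple


# ---------------------------------------------------------------------------
# Validation of corrupted structures


def test_terminal_with_out_edge_flagged(fc):
    bad = copy.deepcopy(fc)
    bad.nodes["t_general"].yes_next = bad.root
    assert any("out-edge" in v for v in validate_flowchart(bad))


def test_removed_node_yields_dangling_and_unreachable(fc):
    bad = copy.deepcopy(fc)
    del bad.nodes["mrna_level"]
    violations = validate_flowchart(bad)
    # independent oracle: referenced-but-undefined vs defined-but-unreferenced
    referenced = {
        e
        for n in bad.nodes.values()
        for e in (n.yes_next, n.no_next)
        if e is not None
    }
    dangling = referenced - set(bad.nodes)
    assert dangling == {"mrna_level"}
    assert any("dangling" in v for v in violations)
    assert any("unreachable" in v for v in violations)


def test_cycle_detected():
    nodes = {
        "a": FlowNode(
            node_id="a", kind=NodeKind.DECISION, question="a?",
            yes_next="b", no_next="t",
        ),
        "b": FlowNode(
            node_id="b", kind=NodeKind.DECISION, question="b?",
            yes_next="a", no_next="t",
        ),
        "t": FlowNode(
            node_id="t", kind=NodeKind.TERMINAL, question="t",
            payload=[PayloadTerm(term="GO:0035195", aspect="BP")],
        ),
    }
    fc = Flowchart(name="c", version="1", root="a", nodes=nodes)
    assert any("cycle" in v for v in validate_flowchart(fc))


# ---------------------------------------------------------------------------
# Traversal vs oracles


def test_step_on_terminal_is_usage_error(fc):
    with pytest.raises(FlowchartUsageError):
        step(fc, "t_general", "yes")


def test_step_reporter_no_gives_no_annotation(fc):
    assert step(fc, "reporter_assay", "no") is Disposition.NO_ANNOTATION


def test_step_root_yes_follows_edge(fc):
    assert step(fc, fc.root, "yes") == fc.node(fc.root).yes_next


def test_enumerate_matches_recursive_oracle_on_fixture(fc):
    assert as_set(enumerate_paths(fc)) == as_set(recursive_paths(fc))
    # leaf count = 1 + number of binary branch points on realized paths
    branch_points = sum(
        1
        for n in fc.nodes.values()
        if n.kind is not NodeKind.TERMINAL
    )
    assert len(enumerate_paths(fc)) == 1 + branch_points


def test_replay_agrees_with_enumerate_on_fixture(fc):
    for vec, outcome in enumerate_paths(fc):
        assert replay(fc, vec) == outcome


@pytest.mark.parametrize("seed", range(10))
def test_randomized_traversal_oracle_equivalence(seed):
    """Iterated step, exhaustive enumeration, and an independently coded
    recursive enumerator agree on randomized flowcharts."""
    rng = random.Random(seed)
    for _ in range(20):
        fc = random_flowchart(12, rng)
        paths = enumerate_paths(fc)
        assert as_set(paths) == as_set(recursive_paths(fc))
        for vec, outcome in paths:
            assert replay(fc, vec) == outcome
        # duplicate-free
        keys = [tuple(vec.items()) for vec, _ in paths]
        assert len(keys) == len(set(keys))
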