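"""Synthetic full-text corpus with known ground truth.

Generates JATS-sectioned articles whose flowchart outcome, filter fate,
GO terms and validated targets are known by construction, together with
the matching gene-mention fixture (annotations-API payload shape). Each
evidence class the curation manual names gets a fixed, unambiguous
keyword sentence — luciferase/3'UTR fusion for the reporter assay,
qRT-PCR mRNA decrease for destabilization, western-blot protein drop
with unchanged mRNA for translational inhibition, "miRNA cluster"
phrasing for cluster studies — so the rule backend recovers the intended
path and end-to-end tests measure pipeline plumbing, not language
understanding. Prose realism is a non-goal.

Identifier lookups used downstream (``data/synthetic_mirna_urs.tsv``,
``data/synthetic_gene_uniprot.tsv``) are synthetic stand-ins with
pattern-valid, invented ids.

Also hosts :func:`random_flowchart`, the randomized-structure generator
used to cross-check the traversal engine against independent enumerators.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from lxml import etree

from .errors import SpecError
from .flowchart import (
    Disposition,
    FlowNode,
    Flowchart,
    NodeKind,
    PayloadTerm,
    validate_flowchart,
)

DATA_DIR = Path(__file__).parent / "data"
SYNTH_URS_TABLE = DATA_DIR / "synthetic_mirna_urs.tsv"
SYNTH_UNIPROT_TABLE = DATA_DIR / "synthetic_gene_uniprot.tsv"
KEYWORD_RULES = DATA_DIR / "keyword_rules.json"

#: Outcomes the curation engine can reach on a filter-passing article.
ENGINE_OUTCOMES = (
    "filtered_no_binding",
    "filtered_cluster",
    "no_annotation",
    "term_0035195",
    "term_0035278",
    "term_0035279",
)
#: Additional corpus-level fates, excluded before the engine ever runs.
EXCLUDED_OUTCOMES = ("multi_mirna", "review_article", "retracted")
ALL_OUTCOMES = ENGINE_OUTCOMES + EXCLUDED_OUTCOMES

#: Default study conditions for an end-to-end curation corpus: the
#: destabilization mechanism dominates annotated outcomes, and a large
#: share of the literature is triaged away before annotation.
DEFAULT_CURATION_COMPOSITION = {
    "filtered_no_binding": 0.20,
    "filtered_cluster": 0.10,
    "no_annotation": 0.20,
    "term_0035195": 0.10,
    "term_0035278": 0.15,
    "term_0035279": 0.25,
}
#: Default composition for corpus-filter exactness checks.
DEFAULT_FILTER_COMPOSITION = {
    "term_0035279": 0.4,
    "multi_mirna": 0.3,
    "review_article": 0.2,
    "retracted": 0.1,
}

MIRNA_POOL = ("hsa-miR-21", "hsa-miR-34a", "mmu-miR-155", "rno-miR-122", "dre-miR-430a")
TARGET_POOL = ("PTEN", "SMAD4", "TP53", "VEGFA", "BCL2", "CDK6", "ZEB1", "SOX4")
DECOY_POOL = ("GAPDH", "ACTB", "RPL13A", "TUBB4B")

HEADING_STYLES = {
    "canonical": ("Introduction", "Methods", "Results", "Discussion"),
    "shouty": ("INTRODUCTION", "MATERIALS AND METHODS", "RESULTS", "DISCUSSION"),
    "exotic": ("Background", "Experimental procedures", "Findings", "Concluding remarks"),
}

_FILLER = (
    "Cell viability was monitored over the course of the experiment.",
    "Transfection efficiency exceeded the threshold required for analysis.",
    "Samples were collected at the indicated time points.",
    "Statistical significance was assessed with standard tests.",
    "All experiments were performed in triplicate.",
)


@dataclass
class SynthSpec:
    """Blueprint for one synthetic article; the outcome uniquely
    determines which keyword blocks are embedded and the seed fixes all
    sampling."""

    outcome: str
    seed: int
    mirna_id: Optional[str] = None
    targets: Optional[List[str]] = None
    decoy_genes: Optional[List[str]] = None
    pub_type: Optional[str] = None
    heading_style: Optional[str] = None
    pmcid: Optional[str] = None
    pmid: Optional[str] = None

    def __post_init__(self):
        if self.outcome not in ALL_OUTCOMES:
            raise SpecError(f"unknown outcome {self.outcome!r}")
        if self.targets is not None:
            annotated = self.outcome.startswith("term_")
            if annotated and not self.targets:
                raise SpecError("annotated outcome requires at least one target")
            if len(self.targets or []) > 4:
                raise SpecError("at most four targets per article")


@dataclass
class GroundTruth:
    expected_status: str
    expected_go_terms: List[str]
    expected_targets: List[str]
    expected_filter_reasons: List[str]
    answer_vector: Dict[str, str]
    mirna_id: str = ""


@dataclass
class CorpusItem:
    spec: SynthSpec
    xml: bytes
    truth: GroundTruth
    gene_fixture: list = field(default_factory=list)


_ANSWER_VECTORS = {
    "filtered_no_binding": {"binding_experiments": "no"},
    "filtered_cluster": {"binding_experiments": "yes", "mirna_cluster": "yes"},
    "no_annotation": {
        "binding_experiments": "yes",
        "mirna_cluster": "no",
        "reporter_assay": "no",
    },
    "term_0035195": {
        "binding_experiments": "yes",
        "mirna_cluster": "no",
        "reporter_assay": "yes",
        "mrna_level": "no",
        "protein_level": "no",
    },
    "term_0035278": {
        "binding_experiments": "yes",
        "mirna_cluster": "no",
        "reporter_assay": "yes",
        "mrna_level": "no",
        "protein_level": "yes",
    },
    "term_0035279": {
        "binding_experiments": "yes",
        "mirna_cluster": "no",
        "reporter_assay": "yes",
        "mrna_level": "yes",
    },
}

_OUTCOME_TERMS = {
    "term_0035195": ["GO:0035195", "GO:1903231"],
    "term_0035278": ["GO:0035278", "GO:1903231"],
    "term_0035279": ["GO:0035279", "GO:1903231"],
}


# ---------------------------------------------------------------------------
# Article generation


def generate_article(spec: SynthSpec) -> Tuple[bytes, GroundTruth, list]:
    """Build one article: JATS XML bytes, its ground truth, and the
    matching annotations-API gene fixture (targets then decoys, in
    first-appearance order). Byte-identical for identical specs."""
    rng = random.Random(spec.seed)
    annotated = spec.outcome.startswith("term_")

    mirna = spec.mirna_id or rng.choice(MIRNA_POOL)
    targets = spec.targets
    if targets is None:
        k = rng.randint(1, 4) if annotated else rng.randint(1, 2)
        targets = list(rng.sample(TARGET_POOL, k))
    decoys = spec.decoy_genes
    if decoys is None:
        decoys = list(rng.sample(DECOY_POOL, rng.randint(1, 3)))
    if annotated and not targets:
        raise SpecError("annotated outcome requires at least one target")
    overlap = set(targets) & set(decoys)
    if overlap:
        raise SpecError(f"targets and decoys overlap: {sorted(overlap)}")

    pub_type = spec.pub_type
    if pub_type is None:
        pub_type = {
            "review_article": "review-article",
            "retracted": "retracted-article",
        }.get(spec.outcome, "research-article")
    style = spec.heading_style or rng.choice(tuple(HEADING_STYLES))
    headings = HEADING_STYLES[style]
    pmcid = spec.pmcid or f"PMC{7000000 + spec.seed % 1000000}"
    pmid = spec.pmid or str(30000000 + spec.seed % 1000000)

    t0 = targets[0]
    title = f"{mirna} regulates {t0} expression in a cellular model"
    abstract = _abstract(spec.outcome, mirna, t0, rng)
    intro = (
        f"MicroRNAs are small regulatory RNAs. Here we study {mirna} and its "
        f"relationship to {t0}. " + rng.choice(_FILLER)
    )
    methods = (
        "Cells were cultured under standard conditions and transfected with "
        f"{mirna} mimics or controls. " + rng.choice(_FILLER)
    )
    results = _results(spec.outcome, mirna, targets, decoys, rng)
    discussion = (
        f"Our observations place {mirna} within the post-transcriptional "
        "regulatory landscape of the cell. " + rng.choice(_FILLER)
    )

    xml = _build_jats(
        pmcid=pmcid,
        pmid=pmid,
        pub_type=pub_type,
        title=title,
        abstract=abstract,
        sections=list(zip(headings, (intro, methods, results, discussion))),
    )

    truth = _ground_truth(spec.outcome, mirna, targets if annotated else [])
    gene_fixture = [
        {
            "pmcid": pmcid,
            "annotations": [
                {"exact": sym, "type": "Gene_Proteins"} for sym in targets + decoys
            ],
        }
    ]
    return xml, truth, gene_fixture


def _abstract(outcome: str, mirna: str, t0: str, rng: random.Random) -> str:
    lead = f"We investigated the role of {mirna} in regulating {t0}."
    if outcome == "filtered_no_binding":
        return (
            f"{lead} Differential expression profiling and in-silico target "
            "prediction suggest a broad regulatory programme."
        )
    if outcome == "filtered_cluster":
        return (
            f"{lead} The miRNA cluster containing this locus acts in concert, "
            "and binding experiments were performed on the clustered transcripts."
        )
    if outcome == "no_annotation":
        return (
            f"{lead} Binding experiments using electrophoretic mobility shift "
            "assays probed the interaction with candidate transcripts."
        )
    if outcome == "multi_mirna":
        other = next(m for m in MIRNA_POOL if m != mirna)
        return (
            f"{lead} We additionally profiled {other} in the same system. "
            "Luciferase reporter binding experiments confirmed direct targeting."
        )
    # annotated outcomes, reviews of them, and retracted research articles
    return (
        f"{lead} Luciferase reporter binding experiments confirmed direct "
        f"targeting of {t0} by {mirna}."
    )


def _results(
    outcome: str,
    mirna: str,
    targets: Sequence[str],
    decoys: Sequence[str],
    rng: random.Random,
) -> str:
    paras: List[str] = []
    if outcome == "filtered_no_binding":
        paras.append(
            "Expression profiling identified a set of differentially "
            f"expressed transcripts after {mirna} perturbation."
        )
    elif outcome == "filtered_cluster":
        paras.append(
            "Members of the miRNA cluster were co-expressed across all "
            "conditions tested."
        )
    elif outcome == "no_annotation":
        paras.append(
            "Electrophoretic mobility shift assays showed complex formation "
            f"between {mirna} and synthetic probes. No functional reporter "
            "readout was obtained."
        )
    else:
        for t in targets:
            paras.append(
                f"A luciferase reporter gene fused to the 3'UTR of {t} showed "
                f"significantly reduced activity when {mirna} was overexpressed."
            )
        if outcome in ("term_0035279", "multi_mirna", "review_article", "retracted"):
            paras.append(
                f"qRT-PCR analysis showed that {targets[0]} mRNA levels "
                f"decreased significantly after {mirna} overexpression."
            )
        elif outcome == "term_0035278":
            paras.append(
                f"Western blot analysis showed that {targets[0]} protein "
                "levels were markedly reduced, while qRT-PCR showed that "
                f"{targets[0]} mRNA levels remained unchanged."
            )
        elif outcome == "term_0035195":
            paras.append(
                "Polysome profiling suggested altered translational "
                "engagement of the target transcript, but neither mRNA nor "
                "protein quantification was performed."
            )
    if decoys:
        paras.append(
            f"Expression of {', '.join(decoys)} was also detected in the "
            "profiling dataset but these genes were not directly examined."
        )
    paras.append(rng.choice(_FILLER))
    return "\n".join(paras)


def _ground_truth(outcome: str, mirna: str, targets: List[str]) -> GroundTruth:
    if outcome in EXCLUDED_OUTCOMES:
        reasons = {
            "multi_mirna": ["multiple_mirnas"],
            "review_article": ["review_article"],
            "retracted": ["retracted"],
        }[outcome]
        return GroundTruth(
            expected_status="excluded",
            expected_go_terms=[],
            expected_targets=[],
            expected_filter_reasons=reasons,
            answer_vector={},
            mirna_id=mirna,
        )
    status = {
        "filtered_no_binding": "filtered",
        "filtered_cluster": "filtered",
        "no_annotation": "no_annotation",
    }.get(outcome, "annotated")
    return GroundTruth(
        expected_status=status,
        expected_go_terms=_OUTCOME_TERMS.get(outcome, []),
        expected_targets=list(targets),
        expected_filter_reasons=[],
        answer_vector=dict(_ANSWER_VECTORS[outcome]),
        mirna_id=mirna,
    )


def _build_jats(
    pmcid: str,
    pmid: str,
    pub_type: str,
    title: str,
    abstract: str,
    sections: List[Tuple[str, str]],
) -> bytes:
    article = etree.Element("article", {"article-type": pub_type})
    front = etree.SubElement(article, "front")
    meta = etree.SubElement(front, "article-meta")
    for id_type, value in (("pmcid", pmcid), ("pmid", pmid)):
        el = etree.SubElement(meta, "article-id", {"pub-id-type": id_type})
        el.text = value
    tg = etree.SubElement(meta, "title-group")
    at = etree.SubElement(tg, "article-title")
    at.text = title
    ab = etree.SubElement(meta, "abstract")
    abp = etree.SubElement(ab, "p")
    abp.text = abstract
    body = etree.SubElement(article, "body")
    for heading, text in sections:
        sec = etree.SubElement(body, "sec")
        t = etree.SubElement(sec, "title")
        t.text = heading
        for para in text.split("\n"):
            p = etree.SubElement(sec, "p")
            p.text = para
    return etree.tostring(
        article, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


# ---------------------------------------------------------------------------
# Corpus generation


def apportion(n: int, composition: Dict[str, float]) -> Dict[str, int]:
    """Exact integer counts per outcome by largest remainder; ties break
    to the first-listed outcome."""
    if n < 1:
        raise SpecError("corpus size must be >= 1")
    total = sum(composition.values())
    if not composition or abs(total - 1.0) > 1e-9:
        raise SpecError(f"composition proportions must sum to 1 (got {total})")
    items = list(composition.items())
    quotas = [n * p for _, p in items]
    counts = [int(q) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(
        range(len(items)), key=lambda i: (-(quotas[i] - counts[i]), i)
    )
    for i in order[:remainder]:
        counts[i] += 1
    return {k: c for (k, _), c in zip(items, counts)}


def generate_corpus(
    n: int,
    composition: Optional[Dict[str, float]] = None,
    seed: int = 0,
) -> List[CorpusItem]:
    """Deterministic corpus of *n* articles with exact per-outcome counts.

    Outcomes are interleaved in a seed-fixed shuffle; per-article seeds
    derive from the master seed, and pmcids are unique by position.
    """
    composition = composition or DEFAULT_CURATION_COMPOSITION
    counts = apportion(n, composition)
    outcomes: List[str] = []
    for outcome, c in counts.items():
        outcomes.extend([outcome] * c)
    master = random.Random(seed)
    master.shuffle(outcomes)
    items: List[CorpusItem] = []
    for i, outcome in enumerate(outcomes):
        spec = SynthSpec(
            outcome=outcome,
            seed=(seed * 1_000_003 + i) % (2**31 - 1),
            pmcid=f"PMC{7000000 + i}",
            pmid=str(30000000 + i),
        )
        xml, truth, fixture = generate_article(spec)
        items.append(CorpusItem(spec=spec, xml=xml, truth=truth, gene_fixture=fixture))
    return items


def write_corpus(items: List[CorpusItem], out_dir) -> None:
    """Materialize a corpus: one XML per article plus ground-truth JSONL
    and per-article gene fixtures."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fixtures = out / "gene_fixtures"
    fixtures.mkdir(exist_ok=True)
    with open(out / "ground_truth.jsonl", "w", encoding="utf-8") as fh:
        for item in items:
            (out / f"{item.spec.pmcid}.xml").write_bytes(item.xml)
            (fixtures / f"{item.spec.pmcid}.json").write_text(
                json.dumps(item.gene_fixture), encoding="utf-8"
            )
            fh.write(
                json.dumps({"pmcid": item.spec.pmcid, **item.truth.__dict__})
                + "\n"
            )


# ---------------------------------------------------------------------------
# Random flowcharts (traversal-oracle test bed)


def random_flowchart(n_decisions: int, rng: random.Random) -> Flowchart:
    """A random valid flowchart with at most *n_decisions* decision nodes.

    Structure is a tree (no sharing), so all nodes are reachable, there
    are no cycles, and at least one terminal is guaranteed (attached post
    hoc if the random dispositions starved every path)."""
    nodes: Dict[str, FlowNode] = {}
    counter = [0]
    terms = ("GO:0035195", "GO:0035278", "GO:0035279")

    def new_terminal() -> str:
        nid = f"t{counter[0]}"
        counter[0] += 1
        nodes[nid] = FlowNode(
            node_id=nid,
            kind=NodeKind.TERMINAL,
            question=nid,
            payload=[
                PayloadTerm(term=rng.choice(terms), aspect="BP"),
                PayloadTerm(term="GO:1903231", aspect="MF"),
            ],
        )
        return nid

    budget = [n_decisions]

    def build() -> str:
        if budget[0] <= 0 or rng.random() < 0.25:
            return new_terminal()
        budget[0] -= 1
        nid = f"d{counter[0]}"
        counter[0] += 1
        node = FlowNode(
            node_id=nid,
            kind=NodeKind.DECISION,
            question=f"question {nid}?",
            prompt=f"question {nid}?",
            section_hint="results",
        )
        nodes[nid] = node
        # one branch always gets an edge so the node is never a dead end
        forced = rng.choice(("yes_next", "no_next"))
        missing = False
        for branch in ("yes_next", "no_next"):
            if branch != forced and rng.random() < 0.2:
                missing = True
            else:
                setattr(node, branch, build())
        if missing:
            node.on_fail = rng.choice(
                (Disposition.FILTERED, Disposition.NO_ANNOTATION)
            )
        return nid

    root = build()
    fc = Flowchart(
        name="random",
        version="0",
        root=root,
        nodes=nodes,
        term_hierarchy={},
    )
    # guarantee a reachable terminal: graft one onto a missing branch
    while any("no terminal" in v for v in validate_flowchart(fc)):
        for node in fc.nodes.values():
            if node.kind is NodeKind.TERMINAL:
                continue
            if node.yes_next is None:
                node.yes_next = new_terminal()
                break
            if node.no_next is None:
                node.no_next = new_terminal()
                break
        fc = Flowchart(
            name="random", version="0", root=root, nodes=nodes, term_hierarchy={}
        )
    return fc
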