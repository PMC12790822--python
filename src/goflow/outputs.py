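"""Serialization of curation runs: records, GPAD 2.0, review export, stats.

The GPAD writer emits candidate annotations in Gene Product Association
Data 2.0: the subject is the miRNA's RNAcentral URS_taxid, the object a
GO term, the reference a PMID, and the target mRNA travels as an
annotation extension (a "has input"-style relation on the UniProtKB
accession). Only annotated records with a resolved URS and a PMID
contribute lines; anything else is skipped with a logged warning rather
than ever producing a malformed line. These are explicitly *candidate*
annotations for curator review, marked by an automatic-assertion
evidence code.

The review export renders one item per annotated record with the full
per-node trace and the four standard reviewer questions, pre-filled
unanswered, in a tool-agnostic JSONL form.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from datetime import date as _date
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Union

from .engine import Annotation, CurationRecord, EngineConfig

log = logging.getLogger(__name__)

GPAD_HEADER = "!gpad-version: 2.0"
GPAD_N_COLUMNS = 12

#: The reviewer question set shown for every annotated record.
REVIEW_QUESTIONS = (
    "Does the reasoning from the model address the questions well?",
    "Does the provided evidence support the decisions given for the questions?",
    "Is the final annotation correct?",
    "Are all targets identified correctly?",
)
REVIEW_FIELDS = ("reasoning_ok", "evidence_ok", "annotation_ok", "targets_ok")


# ---------------------------------------------------------------------------
# Record JSONL


def write_records(records: Iterable[CurationRecord], path: Union[str, Path]) -> int:
    """One JSON object per line; lossless on read-back."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_dict(), ensure_ascii=False) + "\n")
            n += 1
    return n


def read_records(path: Union[str, Path]) -> List[CurationRecord]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(CurationRecord.from_dict(json.loads(line)))
    return out


# ---------------------------------------------------------------------------
# GPAD 2.0


def gpad_line(ann: Annotation, config: EngineConfig, run_date: str) -> str:
    extension = ""
    if ann.target_accession:
        extension = f"{config.extension_relation}(UniProtKB:{ann.target_accession})"
    props = f"target_symbol={ann.target_symbol}"
    cols = [
        f"RNAcentral:{ann.subject_urs_taxid}",  # 1 DB_Object_ID
        "",                                      # 2 Negation
        ann.relation,                            # 3 Relation
        ann.go_term,                             # 4 Ontology_Class_ID
        ann.reference or "",                     # 5 Reference
        ann.evidence_code,                       # 6 Evidence_type
        "",                                      # 7 With_or_From
        "",                                      # 8 Interacting_taxon_ID
        run_date,                                # 9 Date
        ann.assigned_by,                         # 10 Assigned_by
        extension,                               # 11 Annotation_Extensions
        props,                                   # 12 Annotation_Properties
    ]
    return "\t".join(cols)


def write_gpad(
    records: Iterable[CurationRecord],
    path: Union[str, Path],
    config: Optional[EngineConfig] = None,
    run_date: Optional[str] = None,
) -> int:
    """Write annotated records as GPAD 2.0; returns the line count
    (header excluded). Records missing a URS or PMID are skipped with a
    warning — never a malformed line."""
    config = config or EngineConfig()
    run_date = run_date or _date.today().isoformat()
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(GPAD_HEADER + "\n")
        for rec in records:
            if rec.status != "annotated":
                continue
            for ann in rec.annotations:
                if not ann.subject_urs_taxid or not ann.reference:
                    log.warning(
                        "skipping annotation for %s: missing %s",
                        rec.pmcid,
                        "URS" if not ann.subject_urs_taxid else "PMID",
                    )
                    continue
                line = gpad_line(ann, config, run_date)
                problems = validate_gpad_line(line)
                if problems:  # defensive: should be unreachable
                    log.warning("suppressing malformed line for %s: %s", rec.pmcid, problems)
                    continue
                fh.write(line + "\n")
                n += 1
    return n


_CURIE_RE = re.compile(r"^[A-Za-z][\w.]*:\S+$")
_GO_RE = re.compile(r"^GO:\d{7}$")
_ECO_RE = re.compile(r"^ECO:\d{7}$")
_REF_RE = re.compile(r"^(PMID|PMC|DOI|GO_REF):\S+$")
_RELATION_RE = re.compile(r"^RO:\d{7}$")
_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")


def validate_gpad_line(line: str) -> List[str]:
    """Structural GPAD 2.0 check for one data line: exact column count and
    well-formed mandatory fields. Returns problems (empty means valid)."""
    problems: List[str] = []
    cols = line.split("\t")
    if len(cols) != GPAD_N_COLUMNS:
        return [f"expected {GPAD_N_COLUMNS} columns, found {len(cols)}"]
    checks = [
        (0, _CURIE_RE, "DB_Object_ID"),
        (2, _RELATION_RE, "Relation"),
        (3, _GO_RE, "Ontology_Class_ID"),
        (4, _REF_RE, "Reference"),
        (5, _ECO_RE, "Evidence_type"),
        (8, _DATE_RE, "Date"),
    ]
    for idx, pat, name in checks:
        if not pat.match(cols[idx]):
            problems.append(f"column {idx + 1} ({name}) malformed: {cols[idx]!r}")
    if cols[1] not in ("", "NOT"):
        problems.append(f"column 2 (Negation) must be empty or NOT: {cols[1]!r}")
    if not cols[9]:
        problems.append("column 10 (Assigned_by) empty")
    return problems


def validate_gpad_file(path: Union[str, Path]) -> List[str]:
    problems: List[str] = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0] != GPAD_HEADER:
        problems.append("missing !gpad-version: 2.0 header")
    for i, line in enumerate(lines):
        if line.startswith("!") or not line.strip():
            continue
        for p in validate_gpad_line(line):
            problems.append(f"line {i + 1}: {p}")
    return problems


# ---------------------------------------------------------------------------
# Review export


def review_item(rec: CurationRecord) -> dict:
    trace = []
    for d in rec.decisions:
        trace.append(
            {
                "node_id": d.node_id,
                "question": d.prompt_used.split("\n", 1)[0],
                "answer": d.answer,
                "reasoning": d.reasoning,
                "evidence": (
                    {
                        "section": d.evidence.section,
                        "start": d.evidence.start,
                        "end": d.evidence.end,
                        "span": d.evidence.span,
                    }
                    if d.evidence
                    else None
                ),
            }
        )
    return {
        "pmcid": rec.pmcid,
        "trace": trace,
        "annotations": [
            {
                "go_term": a.go_term,
                "aspect": a.aspect,
                "target": a.target_symbol,
                "mirna": a.subject_urs_taxid,
            }
            for a in rec.annotations
        ],
        "questions": {
            fld: {"question": q, "answer": None}
            for fld, q in zip(REVIEW_FIELDS, REVIEW_QUESTIONS)
        },
        "comment": "",
    }


def export_review(
    records: Iterable[CurationRecord], path: Union[str, Path]
) -> int:
    """One review item per *annotated* record, questions unanswered."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            if rec.status != "annotated":
                continue
            fh.write(json.dumps(review_item(rec), ensure_ascii=False) + "\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# Summary statistics


@dataclass
class RunSummary:
    articles_processed: int = 0
    status_tallies: Dict[str, int] = field(default_factory=dict)
    term_counts: Dict[str, int] = field(default_factory=dict)
    taxon_counts: Dict[str, int] = field(default_factory=dict)

    def __add__(self, other: "RunSummary") -> "RunSummary":
        def merge(a: Dict[str, int], b: Dict[str, int]) -> Dict[str, int]:
            out = dict(a)
            for k, v in b.items():
                out[k] = out.get(k, 0) + v
            return out

        return RunSummary(
            articles_processed=self.articles_processed + other.articles_processed,
            status_tallies=merge(self.status_tallies, other.status_tallies),
            term_counts=merge(self.term_counts, other.term_counts),
            taxon_counts=merge(self.taxon_counts, other.taxon_counts),
        )

    def to_dict(self) -> dict:
        return {
            "articles_processed": self.articles_processed,
            "status_tallies": dict(sorted(self.status_tallies.items())),
            "term_counts": dict(sorted(self.term_counts.items())),
            "taxon_counts": dict(sorted(self.taxon_counts.items())),
        }


def summarize(records: Iterable[CurationRecord]) -> RunSummary:
    """Tally statuses, per-GO-term annotation counts, and per-taxon
    counts (taxon read from the URS_taxid suffix)."""
    s = RunSummary()
    for rec in records:
        s.articles_processed += 1
        s.status_tallies[rec.status] = s.status_tallies.get(rec.status, 0) + 1
        for ann in rec.annotations:
            s.term_counts[ann.go_term] = s.term_counts.get(ann.go_term, 0) + 1
            if ann.subject_urs_taxid:
                taxon = ann.subject_urs_taxid.rsplit("_", 1)[1]
                s.taxon_counts[taxon] = s.taxon_counts.get(taxon, 0) + 1
    return s
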