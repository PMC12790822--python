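"""Corpus construction: miRNA identifier detection and article triage.

Only articles that can be curated cleanly enter the pipeline: they must
mention exactly one miRNA, named with an organism-prefixed identifier from
an authoritative naming scheme (miRBase ``hsa-miR-21-5p`` style or
MirGeneDB ``Hsa-Mir-21`` style), and must be research articles — reviews
and retracted papers are unsuitable for GO curation and are excluded.

Identifier distinctness is computed at the gene level: the -5p/-3p arm
suffixes of one hairpin collapse to a single miRNA, while different
numbers or paralog copies (miR-21 vs miR-22, mir-21-1 vs mir-21-2) stay
distinct. The patterns err strict — detecting a scheme identifier is a
precision-first signal, so loose alias forms are deliberately not matched.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple, Union

from .articles import Article
from .errors import LookupTableError

URS_TAXID_RE = re.compile(r"^URS[0-9A-F]{10}_\d+$")

# miRBase: lowercase 3-4 letter organism prefix, miR/mir/let/lin stem,
# number, optional letter variant, optional -N paralog copy, optional arm.
MIRBASE_RE = re.compile(
    r"(?<![A-Za-z0-9-])"
    r"(?P<prefix>[a-z]{3,4})-(?P<stem>miR|mir|let|lin)-"
    r"(?P<num>\d+[a-z]?)(?P<paralog>-\d+)?(?P<arm>-[35]p)?"
    r"(?![A-Za-z0-9])"
)

# MirGeneDB: capitalized 3-4 letter prefix, Mir/Let stem, number, optional
# -Pn paralog, optional _5p/_3p arm.
MIRGENEDB_RE = re.compile(
    r"(?<![A-Za-z0-9-])"
    r"(?P<prefix>[A-Z][a-z]{2,3})-(?P<stem>Mir|Let)-"
    r"(?P<num>\d+)(?P<paralog>-P\d+[a-z]?)?(?P<arm>_[35]p)?"
    r"(?![A-Za-z0-9])"
)

#: NCBI taxon ids for common organism prefixes (extend via lookup tables
#: for exotic species; unknown prefixes resolve to None).
PREFIX_TAXON: Dict[str, int] = {
    "hsa": 9606,
    "mmu": 10090,
    "rno": 10116,
    "dme": 7227,
    "cel": 6239,
    "dre": 7955,
    "gga": 9031,
    "bta": 9913,
    "ssc": 9823,
    "oar": 9940,
    "ath": 3702,
    "osa": 4530,
}

FILTER_REASONS = ("multiple_mirnas", "no_mirna", "review_article", "retracted", "not_research")

_REVIEW_TYPES = {"review-article", "review", "systematic-review"}
_RETRACTED_TYPES = {"retraction", "retracted-publication", "retracted-article"}
_NON_RESEARCH_TYPES = {"editorial", "letter", "correction", "news", "book-review"}


@dataclass(frozen=True)
class MirnaMention:
    raw_text: str
    scheme: str  # "mirbase" | "mirgenedb"
    organism_prefix: str
    normalized_id: str
    urs_taxid: Optional[str] = None
    unresolved: bool = False

    @property
    def taxon(self) -> Optional[int]:
        if self.urs_taxid:
            return int(self.urs_taxid.rsplit("_", 1)[1])
        return PREFIX_TAXON.get(self.organism_prefix.lower())


@dataclass
class FilterReport:
    pmcid: str
    passed: bool
    reasons: List[str] = field(default_factory=list)
    distinct_mirnas: int = 0

    def __post_init__(self):
        assert self.passed == (not self.reasons)


# ---------------------------------------------------------------------------
# Identifier detection


def detect_mirna_ids(text: str) -> List[MirnaMention]:
    """All non-overlapping scheme-identifier matches, in text order.

    Normalization lowercases the stem and drops the arm suffix; paralog
    copies and letter variants are kept, so distinctness (on
    ``normalized_id``) is gene-level.
    """
    hits: List[Tuple[int, int, MirnaMention]] = []
    for m in MIRBASE_RE.finditer(text):
        hits.append((m.start(), m.end(), _mention_from(m, "mirbase")))
    for m in MIRGENEDB_RE.finditer(text):
        hits.append((m.start(), m.end(), _mention_from(m, "mirgenedb")))
    hits.sort(key=lambda h: (h[0], -h[1]))
    out: List[MirnaMention] = []
    last_end = -1
    for start, end, mention in hits:
        if start < last_end:
            continue
        out.append(mention)
        last_end = end
    return out


def _mention_from(m: re.Match, scheme: str) -> MirnaMention:
    prefix = m.group("prefix")
    stem = m.group("stem").lower()
    if stem == "mir":  # both miR and Mir normalize to mir
        stem = "mir"
    num = m.group("num").lower()
    paralog = (m.group("paralog") or "").lower().replace("_", "-")
    normalized = f"{prefix.lower()}-{stem}-{num}{paralog}"
    return MirnaMention(
        raw_text=m.group(0),
        scheme=scheme,
        organism_prefix=prefix,
        normalized_id=normalized,
    )


def distinct_mirnas(mentions: Iterable[MirnaMention]) -> List[str]:
    seen: List[str] = []
    for m in mentions:
        if m.normalized_id not in seen:
            seen.append(m.normalized_id)
    return seen


# ---------------------------------------------------------------------------
# Article / corpus filtering


def filter_article(article: Article) -> FilterReport:
    """Apply the corpus-construction rules to one parsed article."""
    reasons: List[str] = []
    types = {t.lower() for t in article.pub_types}
    if types & _REVIEW_TYPES:
        reasons.append("review_article")
    if (types & _RETRACTED_TYPES) or article.retraction_linked:
        reasons.append("retracted")
    if types & _NON_RESEARCH_TYPES:
        reasons.append("not_research")
    ids = distinct_mirnas(detect_mirna_ids(article.full_text()))
    if len(ids) == 0:
        reasons.append("no_mirna")
    elif len(ids) > 1:
        reasons.append("multiple_mirnas")
    return FilterReport(
        pmcid=article.pmcid,
        passed=not reasons,
        reasons=reasons,
        distinct_mirnas=len(ids),
    )


def filter_corpus(
    articles: Iterable[Article],
) -> Tuple[List[Article], List[FilterReport]]:
    """Filter a corpus; one report per input article, order preserved."""
    kept: List[Article] = []
    reports: List[FilterReport] = []
    for art in articles:
        rep = filter_article(art)
        reports.append(rep)
        if rep.passed:
            kept.append(art)
    return kept, reports


# ---------------------------------------------------------------------------
# URS resolution


def load_urs_table(path: Union[str, Path]) -> Dict[str, str]:
    """Load a 2-column TSV (normalized_id, urs_taxid) with integrity
    checks: header required, URS pattern enforced, duplicate keys fatal."""
    table: Dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or set(reader.fieldnames) < {
            "normalized_id",
            "urs_taxid",
        }:
            raise LookupTableError(
                f"{path}: header must name normalized_id and urs_taxid"
            )
        for i, row in enumerate(reader, start=2):
            key, val = row["normalized_id"].strip(), row["urs_taxid"].strip()
            if not URS_TAXID_RE.match(val):
                raise LookupTableError(f"{path}:{i}: malformed URS_taxid {val!r}")
            if key in table and table[key] != val:
                raise LookupTableError(f"{path}:{i}: duplicate key {key!r}")
            table[key] = val
    return table


def resolve_urs(mention: MirnaMention, lookup: Dict[str, str]) -> MirnaMention:
    """Attach the RNAcentral URS_taxid for a mention, or flag it
    unresolved (the record stays usable; GPAD emission is blocked)."""
    urs = lookup.get(mention.normalized_id)
    if urs is None:
        return replace(mention, urs_taxid=None, unresolved=True)
    return replace(mention, urs_taxid=urs, unresolved=False)
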