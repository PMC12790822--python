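"""Target-gene resolution constrained to externally mined mention lists.

Verbatim substring extraction guarantees evidence fidelity but not clean
entity boundaries, so target genes are never free-text extracted: the
backend chooses among the gene/protein symbols a text-mining service
already found in the article (the annotations-API payload shape of
EuropePMC), one symbol per constrained-choice round, until it signals
``DONE``. A ``NOT_IN_LIST`` sentinel lets the backend surface the known
failure mode where the true target is missing from the mined list, rather
than being forced onto a wrong symbol.

Chosen symbols are mapped to UniProtKB accessions through a (symbol,
taxon) lookup table; a miss is flagged, not fatal — the annotation is
emitted with the bare symbol and marked accordingly.
"""

from __future__ import annotations

import csv
import json
import re
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple, Union

from . import backends
from .backends import (
    Backend,
    ChoiceRequest,
    DONE_SENTINEL,
    NOT_IN_LIST_SENTINEL,
)
from .errors import GeneListParseError, LookupTableError

DEFAULT_MAX_TARGETS = 4

ANNOTATIONS_API = (
    "https://www.ebi.ac.uk/europepmc/annotations_api/annotationsByArticleIds"
)


@dataclass
class GeneMentionList:
    pmcid: str
    symbols: List[str]
    source: str = "fixture"  # "live_api" | "fixture"


@dataclass
class TargetSet:
    validated: List[Tuple[str, Optional[str]]] = field(default_factory=list)
    rejected: List[Tuple[str, str]] = field(default_factory=list)
    unresolvable: bool = False
    note: str = ""
    #: every selection the backend made, in order, including the final
    #: sentinel — kept so a record can be replayed round-for-round
    rounds: List[str] = field(default_factory=list)

    @property
    def symbols(self) -> List[str]:
        return [s for s, _ in self.validated]


# ---------------------------------------------------------------------------
# Mention-list clients


def parse_gene_annotations(payload: object, pmcid: str = "") -> List[str]:
    """Extract ordered, de-duplicated gene symbols from an
    annotations-API JSON payload (a list of per-article objects, each with
    an ``annotations`` array whose items carry an ``exact`` string)."""
    if isinstance(payload, dict):
        payload = [payload]
    if not isinstance(payload, list):
        raise GeneListParseError("payload is neither object nor list", path="/")
    symbols: List[str] = []
    for i, entry in enumerate(payload):
        if not isinstance(entry, dict) or "annotations" not in entry:
            raise GeneListParseError(
                "entry missing 'annotations' field", path=f"/{i}"
            )
        anns = entry["annotations"]
        if not isinstance(anns, list):
            raise GeneListParseError("'annotations' is not a list", path=f"/{i}/annotations")
        for j, ann in enumerate(anns):
            exact = ann.get("exact") if isinstance(ann, dict) else None
            if not isinstance(exact, str) or not exact.strip():
                raise GeneListParseError(
                    "annotation missing 'exact' text", path=f"/{i}/annotations/{j}"
                )
            sym = exact.strip()
            if sym not in symbols:
                symbols.append(sym)
    return symbols


class FixtureGeneClient:
    """Serves annotations-API payloads from an in-memory mapping or a
    directory of ``<PMCID>.json`` files."""

    source = "fixture"

    def __init__(self, store: Union[Mapping[str, object], str, Path]):
        self._mapping = store if isinstance(store, Mapping) else None
        self._dir = Path(store) if not isinstance(store, Mapping) else None

    def get_annotations(self, pmcid: str) -> object:
        if self._mapping is not None:
            if pmcid not in self._mapping:
                raise GeneListParseError(f"no fixture payload for {pmcid}")
            return self._mapping[pmcid]
        path = self._dir / f"{pmcid}.json"
        if not path.exists():
            raise GeneListParseError(f"no fixture payload for {pmcid} at {path}")
        return json.loads(path.read_text(encoding="utf-8"))


class LiveGeneClient:
    """Live annotations-API client (opt-in; never used in tests/CI)."""

    source = "live_api"

    def __init__(self, base_url: str = ANNOTATIONS_API, timeout: float = 30.0):
        self.base_url = base_url
        self.timeout = timeout

    def get_annotations(self, pmcid: str) -> object:  # pragma: no cover - network
        params = urllib.parse.urlencode(
            {
                "articleIds": f"PMC:{pmcid.removeprefix('PMC')}",
                "type": "Gene_Proteins",
                "provider": "Europe PMC",
                "format": "JSON",
            }
        )
        with urllib.request.urlopen(
            f"{self.base_url}?{params}", timeout=self.timeout
        ) as resp:
            return json.loads(resp.read().decode("utf-8"))


def fetch_gene_list(pmcid: str, client) -> GeneMentionList:
    """Fetch and parse the gene/protein mention list for an article."""
    if not re.match(r"^PMC\d+$", pmcid):
        raise ValueError(f"malformed pmcid {pmcid!r}")
    payload = client.get_annotations(pmcid)
    symbols = parse_gene_annotations(payload, pmcid=pmcid)
    return GeneMentionList(pmcid=pmcid, symbols=symbols, source=client.source)


# ---------------------------------------------------------------------------
# Constrained target selection


def select_targets(
    context_text: str,
    mentions: GeneMentionList,
    backend: Backend,
    max_targets: int = DEFAULT_MAX_TARGETS,
) -> TargetSet:
    """Select validated targets by repeated constrained choice.

    Each round offers the remaining symbols plus the ``DONE`` and
    ``NOT_IN_LIST`` sentinels; selections past ``max_targets`` are kept in
    the rejected list with reason "limit". Zero selections, an empty
    mention list, or ``NOT_IN_LIST`` mark the set unresolvable.
    """
    ts = TargetSet()
    if not mentions.symbols:
        ts.unresolvable = True
        ts.note = "empty gene mention list"
        return ts
    remaining = list(dict.fromkeys(mentions.symbols))
    picked: List[str] = []
    for round_no in range(len(remaining) + 2):
        options = tuple(remaining) + (DONE_SENTINEL, NOT_IN_LIST_SENTINEL)
        req = ChoiceRequest(
            key=f"{backends.TARGET_SELECT_KEY}#{round_no}",
            prompt=(
                "Select the next gene symbol whose mRNA is a validated "
                "target of the miRNA in the text below, DONE if all "
                "validated targets have been selected, or NOT_IN_LIST if a "
                "validated target is missing from the candidate list.\n"
                f"Already selected: {', '.join(picked) or '(none)'}\n\n"
                + context_text
            ),
            options=options,
        )
        resp = backends.choose(backend, req)
        ts.rounds.append(resp.selected)
        if resp.selected == DONE_SENTINEL:
            break
        if resp.selected == NOT_IN_LIST_SENTINEL:
            ts.unresolvable = True
            ts.note = "backend reports a validated target absent from the mined list"
            break
        remaining.remove(resp.selected)
        picked.append(resp.selected)
        if len(ts.validated) >= max_targets:
            ts.rejected.append((resp.selected, "limit"))
        else:
            ts.validated.append((resp.selected, None))
        if not remaining:
            break
    if not ts.validated and not ts.unresolvable:
        ts.unresolvable = True
        ts.note = ts.note or "no validated target selected"
    return ts


# ---------------------------------------------------------------------------
# UniProt mapping


def load_uniprot_table(path: Union[str, Path]) -> Dict[Tuple[str, int], str]:
    """Load a 3-column TSV (symbol, taxon, accession); duplicate
    (symbol, taxon) keys with conflicting accessions are fatal."""
    table: Dict[Tuple[str, int], str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or set(reader.fieldnames) < {
            "symbol",
            "taxon",
            "accession",
        }:
            raise LookupTableError(f"{path}: header must name symbol, taxon, accession")
        for i, row in enumerate(reader, start=2):
            key = (row["symbol"].strip(), int(row["taxon"]))
            acc = row["accession"].strip()
            if key in table and table[key] != acc:
                raise LookupTableError(f"{path}:{i}: duplicate key {key!r}")
            table[key] = acc
    return table


def map_to_uniprot(
    symbol: str, lookup: Mapping[Tuple[str, int], str], taxon: Optional[int]
) -> Optional[str]:
    """Exact (symbol, taxon) lookup; a miss returns None (flagged by the
    caller, annotation emitted with symbol only)."""
    if taxon is None:
        return None
    return lookup.get((symbol, taxon))


def resolve_target_set(
    ts: TargetSet,
    lookup: Mapping[Tuple[str, int], str],
    taxon: Optional[int],
) -> TargetSet:
    """Fill in UniProtKB accessions for validated symbols in place."""
    ts.validated = [
        (sym, map_to_uniprot(sym, lookup, taxon)) for sym, _ in ts.validated
    ]
    return ts
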