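# goflow

Flowchart-guided GO biocuration of miRNA gene-silencing literature.

Manual curation of microRNA function into the Gene Ontology cannot keep
pace with the literature: most published miRNA–target experiments never
become structured annotations. For the narrow, well-standardized slice
of biology covered by the GO consortium's miRNA curation flowchart —
miRNA-mediated post-transcriptional gene silencing and its two mechanism
children — the curation decision process can be executed mechanically:
each flowchart node is a yes/no question about a specific evidence class
(reporter assay, mRNA quantification, protein quantification), and the
answers determine the GO term.

`goflow` is an engine for exactly that. It parses JATS/EuropePMC
full-text XML into sectioned articles, triages the corpus (one
organism-prefixed miRBase/MirGeneDB miRNA identifier per article; no
reviews or retractions), then walks the article through the flowchart
using a *constrained backend*: every answer is a forced choice from a
fixed option set, and every piece of evidence is a verbatim substring of
the article with byte-exact offsets, verified before it enters the
record. The product is a candidate annotation triple — miRNA
(RNAcentral `URS_taxid`), GO term, target mRNA (UniProtKB) — together
with a fully replayable, human-reviewable reasoning trace per node. It
is a curator-assistant pipeline: output is explicitly candidate
material for expert review, never direct database content.

## The core procedure

For an article that passes triage, with flowchart `F`, backend `B`, and
section budget `β`:

1. Resolve canonical section labels to the article's real headings by
   zero-shot constrained choice (heading list + `NONE`).
2. From the root of `F`: assemble the node prompt (manual guidance +
   lazily loaded hinted section, charged once against `β`), ask `B` for
   a constrained yes/no, capture a verified evidence span at decision
   nodes, and follow the answered edge; missing branches carry explicit
   dispositions (`filtered` / `no_annotation`).
3. At a terminal, select validated targets by repeated constrained
   choice over the externally mined gene-mention list (+`DONE`,
   `NOT_IN_LIST`), then emit one annotation per (payload term × target).
4. Finalize with integrity checks: the recorded answer vector must
   replay through `F` to the recorded outcome, and a record may never
   carry the parent term `GO:0035195` when its answers satisfy a child
   path (`GO:0035278` inhibition of translation, `GO:0035279` mRNA
   destabilization). All terminals co-annotate `GO:1903231` (MF).

Two deterministic, model-free backends ship with the package (a
scripted replay backend and a regex keyword backend); any
constrained-decoding model adapter can stand behind the same contract.
See `docs/methods.md` for the model, assumptions, and design choices.

## Worked example

Curate a 50-article synthetic corpus (known ground truth, keyword
backend) and export GPAD:

```python
import json
from goflow import (load_bundled_flowchart, parse_jats, KeywordBackend,
                    run_flowchart, load_urs_table, load_uniprot_table,
                    GeneMentionList, summarize, write_gpad)
from goflow.synth import (generate_corpus, KEYWORD_RULES, SYNTH_URS_TABLE,
                          SYNTH_UNIPROT_TABLE)

fc = load_bundled_flowchart()
backend = KeywordBackend.from_file(KEYWORD_RULES)
urs = load_urs_table(SYNTH_URS_TABLE)
uniprot = load_uniprot_table(SYNTH_UNIPROT_TABLE)

records = []
for item in generate_corpus(50, seed=7):
    article = parse_jats(item.xml)
    mentions = GeneMentionList(
        pmcid=article.pmcid,
        symbols=[a["exact"] for a in item.gene_fixture[0]["annotations"]],
    )
    records.append(run_flowchart(article, fc, backend,
                                 gene_mentions=mentions,
                                 urs_lookup=urs, uniprot_lookup=uniprot))

print(json.dumps(summarize(records).to_dict(), indent=2))
print("gpad lines:", write_gpad(records, "demo.gpad"))
```

prints

```
{
  "articles_processed": 50,
  "status_tallies": {
    "annotated": 25,
    "filtered": 15,
    "no_annotation": 10
  },
  "term_counts": {
    "GO:0035195": 10,
    "GO:0035278": 15,
    "GO:0035279": 29,
    "GO:1903231": 54
  },
  "taxon_counts": {
    "10090": 22,
    "10116": 6,
    "7955": 24,
    "9606": 56
  }
}
gpad lines: 108
```

Half the corpus ends annotated; the rest is triaged (`filtered`: no
binding experiments, or a miRNA-cluster study) or traced without an
annotation (`no_annotation`: no acceptable reporter assay, or no
validated target). Term counts tally per-annotation GO terms — every
annotated record pairs one BP mechanism term with the MF co-term
`GO:1903231`, and multi-target articles contribute one annotation per
target, which is why 108 GPAD lines arise from 25 articles. A line looks
like

```
RNAcentral:URS00000A34A0_9606		RO:0002331	GO:0035278	PMID:30000001	ECO:0000203			2026-09-24	goflow	RO:0002233(UniProtKB:P90005)	target_symbol=BCL2
```

and each record keeps its per-node trace, e.g. at the reporter-assay
node:

> A luciferase reporter gene fused to the 3'UTR of BCL2 showed
> significantly reduced activity when hsa-miR-34a was overexpressed.

The same pipeline is available from the shell: `goflow synth`,
`goflow filter`, `goflow curate`, `goflow export`,
`goflow validate-flowchart`, `goflow inspect-article` (see `--help`).

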