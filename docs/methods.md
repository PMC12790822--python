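# Methods

## The curation model

`goflow` executes an expert curation flowchart over full-text articles to
produce candidate Gene Ontology (GO) annotations for miRNA-mediated
post-transcriptional gene silencing. The annotation unit is the triple
(miRNA, GO term, target mRNA): the subject is an RNAcentral `URS_taxid`
identifier, the object one of three Biological Process terms plus a
Molecular Function co-term, and the target a gene symbol with an optional
UniProtKB accession.

The flowchart is a rooted binary decision structure. Two cheap *filter*
nodes triage articles before the evidence-bearing tree: articles that do
not describe miRNA–mRNA binding experiments, and miRNA-cluster studies
(clusters act in concert and need a different curation model), are set
aside. Three *decision* nodes then encode the curation manual's evidence
ladder:

1. **Functional interaction by reporter assay?** The gateway question.
   Acceptable evidence is a luciferase reporter fused to the target's
   3'UTR (or CRISPR deletion of the miRNA response element with protein
   readout). Without it no annotation is made.
2. **Target mRNA level decreases (qRT-PCR or equivalent)?** If yes, the
   mechanism is mRNA destabilization → `GO:0035279`.
3. **Protein decreases while mRNA is unchanged?** If yes, the mechanism
   is inhibition of translation → `GO:0035278`. Otherwise only the
   parent term `GO:0035195` is supported.

Every terminal also carries `GO:1903231` (mRNA base-pairing
post-transcriptional repressor activity, MF). `GO:0035278` and
`GO:0035279` are `is_a` children of `GO:0035195`; because each terminal
is a leaf carrying exactly one BP term, the structure itself guarantees
that a record can never "round down" to the parent when its recorded
answers satisfy a child path — the finalizer additionally replays the
answer vector and raises a specificity error on any such mismatch.

The published GO-wiki flowchart exists only as a figure; the bundled
JSON fixture is a reconstruction from the manual's evidence classes and
should be read as such. The machine-readable schema
(`data/flowchart.schema.json`) is this package's own definition.

## Constrained backends

All model interaction goes through a two-operation contract:

* **Constrained choice** — the backend must return one of the offered
  options verbatim (the analogue of masking the decoding token space to
  the option set). Yes/no flowchart answers, zero-shot heading
  normalization, and target selection all use this primitive.
* **Constrained span** — the backend must return a verbatim substring of
  the offered source with 0-based half-open character offsets.

Shared verifier wrappers re-check both invariants on every call and
raise a contract violation rather than repairing anything; an evidence
"quote" that is not byte-exactly `source[start:end]` never enters a
record. Offsets refer to the normalized section text (Unicode NFC,
space/tab runs collapsed, paragraph breaks kept as single newlines), so
they stay valid across serialization.

Two deterministic backends ship with the package. The *scripted* backend
answers from an explicit key→answer table and is the replay mechanism:
any curation record converts to a script that reproduces the identical
record (timestamp aside). The *keyword* backend answers from an ordered
regex rule table (first match wins; rules match the article text portion
of a prompt, never the node guidance, which itself names the assay
vocabulary) and serves as the deterministic stand-in for a reasoning
model on synthetic articles. A real constrained-decoding model adapter
is a plug-in behind the same contract; API-hosted models are
unsupported by design, since the contract requires control over token
sampling.

Reasoning traces are generated under a 1024-token cap (the verifier
enforces `reasoning_tokens_used ≤ cap`) but stored verbatim and uncapped
in records. Token counting defaults to whitespace splitting — counts are
model-specific in reality, and tests need a model-free, deterministic
counter; adapters may override it.

## Section serving and budgets

The engine works on article sections, not whole texts. Canonical labels
(`abstract`, `introduction`, `methods`, `results`, `discussion`) are
resolved to the article's actual headings by constrained choice over the
real headings plus a `NONE` sentinel; claimed headings are withheld from
later choices, making the index injective by construction. Section text
is loaded lazily and charged once against a run budget (default 64 000
context tokens, mirroring a single-GPU context window; 4 000 tokens
offered per evidence extraction). Oversized sections are truncated to a
paragraph-aligned prefix; a missing canonical section falls back to the
abstract and then the full body, flagged in the load log rather than
silently served. Supplementary files are never fetched — evidence that
exists only there surfaces as an absent-evidence case.

## Corpus rules

Articles enter curation only if they (a) mention exactly one distinct
miRNA named with an organism-prefixed miRBase (`hsa-miR-21-5p`) or
MirGeneDB (`Hsa-Mir-21`) identifier, and (b) are research articles —
reviews and retracted papers are excluded. The identifier patterns are
deliberately strict (precision over recall): alias forms without an
organism prefix do not count. Distinctness is gene-level — `-5p`/`-3p`
arms of one hairpin collapse, while numbers, letter variants and paralog
copies stay distinct. The naming authorities do not prescribe arm
handling for "one miRNA per article"; gene-level counting is this
package's documented choice. The normative examples live in
`data/mirna_id_examples.json`.

Identifier-to-URS and symbol-to-UniProt lookups are 2/3-column TSVs with
load-time integrity checks (pattern validity, duplicate keys fatal). The
shipped tables (`synthetic_*.tsv`) are synthetic stand-ins with invented,
pattern-valid ids — real deployments point at RNAcentral/UniProt dumps.

## Target selection

Targets are never free-text extracted. The backend selects among the
gene/protein symbols an external text-mining service already found in
the article (the EuropePMC annotations-API payload shape), one symbol
per round plus `DONE`/`NOT_IN_LIST` sentinels, up to 4 validated targets
by default (selections beyond the cap are kept as rejected with reason
"limit"). `NOT_IN_LIST` exists so the backend can surface the known
failure mode where the true target is missing from the mined list
instead of being forced onto a wrong symbol; zero validated targets
downgrades the record to `no_annotation` while preserving the full
trace, because annotations of this type are target-anchored. The live
API client is opt-in; tests and offline runs use fixture payloads.

## Outputs

Records serialize losslessly to JSONL. GPAD 2.0 lines are emitted only
for annotated records with a resolved URS and PMID; the target travels
as an annotation extension (`RO:0002233`, "has input") on the UniProtKB
accession, with the bare symbol always present in the properties column.
Defaults — relation `RO:0002331` (involved_in) for BP, `RO:0002327`
(enables) for MF, evidence code `ECO:0000203` (automatic assertion),
`Assigned_by: goflow` — are configuration, not policy: these are
explicitly *candidate* annotations requiring curator review, and GO does
not accept unreviewed machine annotations. A shipped line validator
checks column count and mandatory-field shape for every emitted line.
The review export renders the per-node trace with the four standard
reviewer questions (reasoning, evidence, annotation, targets),
pre-filled unanswered, as tool-agnostic JSONL.

## Synthetic corpus

The generator emulates what the pipeline consumes: JATS-sectioned
articles with controllable heading styles (canonical, upper-case
"MATERIALS AND METHODS" style, and exotic variants to exercise heading
normalization), a single embedded miRNA identifier, 1–4 validated
targets plus decoy genes, and publication-type metadata. Each flowchart
outcome embeds one fixed, unambiguous keyword sentence per evidence
class (luciferase/3'UTR fusion; qRT-PCR mRNA decrease; western-blot
protein drop with unchanged mRNA; "miRNA cluster" phrasing), and the
matching gene fixture lists targets before decoys. Corpus composition
uses largest-remainder apportionment, so integer counts per outcome are
exact; all sampling derives from the master seed and same-seed corpora
are byte-identical.

Because the keyword signal is unambiguous by construction, end-to-end
recovery measures *pipeline plumbing* — traversal, caching, evidence
offsets, target constraint, serialization — not language understanding.
Passing says nothing about how a real model handles real prose, figure
data, contradictory assays, or evidence split across sections; those
remain properties of the model behind the contract. Default study
conditions: curation corpora of 100 articles across all six outcomes
(destabilization the most frequent annotated mechanism, a majority of
articles triaged away), and filter corpora of 40 pass / 30 multi-miRNA /
20 review / 10 retracted.

## Numerical and design choices

* Temperature 0 and deterministic backends everywhere; a choice is a
  pure function of (key, prompt, options).
* Evidence is captured at decision nodes only; filters are cheap triage.
* Rule order in the keyword backend is semantics (first match wins);
  the no-match default is "no".
* Degenerate inputs: a flowchart whose root is a terminal yields one
  empty-vector path; an empty corpus filters to `([], [])`; an empty
  mention list is unresolvable, not an error.
* Apportionment ties break to the first-listed outcome.
* Randomized-flowchart tests generate trees (no sharing), up to 12
  decision nodes, with at least one wired branch per decision and a
  grafted terminal if random dispositions starve every path.
* Problem sizes in the checked runs — 200 random flowcharts, 20 corpora
  of 100 articles, 20 filter corpora — keep the full suite under ten
  seconds while exercising every outcome class and ≥20 seeds.

## Known limitations

* The flowchart fixture is a reconstruction of published guidance, not a
  transcription of the original figure.
* PDF input, figure/table understanding, reference lists, and
  supplementary material are out of scope.
* One miRNA per article: multi-miRNA and cluster papers are excluded
  upstream, so multi-subject annotation is unsupported.
* Gene symbols come from an external mention list; a target the miner
  missed can only be surfaced as `NOT_IN_LIST`, never recovered.
* The shipped lookup tables are synthetic; GPAD output is only as good
  as the tables provided.
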