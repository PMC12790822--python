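{
  "name": "mirna-gene-silencing",
  "version": "1.0",
  "root": "binding_experiments",
  "nodes": {
    "binding_experiments": {
      "kind": "filter",
      "question": "Does the article describe miRNA-mRNA binding experiments?",
      "section_hint": "abstract",
      "yes_next": "mirna_cluster",
      "on_fail": "filtered"
    },
    "mirna_cluster": {
      "kind": "filter",
      "question": "Is this a study of a miRNA cluster acting in concert?",
      "section_hint": "abstract",
      "no_next": "reporter_assay",
      "on_fail": "filtered"
    },
    "reporter_assay": {
      "kind": "decision",
      "question": "Functional interaction by reporter assay?",
      "section_hint": "results",
      "yes_next": "mrna_level",
      "on_fail": "no_annotation"
    },
    "mrna_level": {
      "kind": "decision",
      "question": "Does the target mRNA level decrease (qRT-PCR or equivalent)?",
      "section_hint": "results",
      "yes_next": "t_destabilization",
      "no_next": "protein_level"
    },
    "protein_level": {
      "kind": "decision",
      "question": "Does the target protein level decrease while the mRNA level is unchanged?",
      "section_hint": "results",
      "yes_next": "t_translation",
      "no_next": "t_general"
    },
    "t_destabilization": {
      "kind": "terminal",
      "question": "miRNA-mediated gene silencing by mRNA destabilization",
      "payload": [
        {"term": "GO:0035279", "aspect": "BP"},
        {"term": "GO:1903231", "aspect": "MF"}
      ]
    },
    "t_translation": {
      "kind": "terminal",
      "question": "miRNA-mediated gene silencing by inhibition of translation",
      "payload": [
        {"term": "GO:0035278", "aspect": "BP"},
        {"term": "GO:1903231", "aspect": "MF"}
      ]
    },
    "t_general": {
      "kind": "terminal",
      "question": "miRNA-mediated post-transcriptional gene silencing",
      "payload": [
        {"term": "GO:0035195", "aspect": "BP"},
        {"term": "GO:1903231", "aspect": "MF"}
      ]
    }
  },
  "term_hierarchy": {
    "GO:0035278": "GO:0035195",
    "GO:0035279": "GO:0035195"
  }
}
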