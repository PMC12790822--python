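[
  {"pattern": "(?i)miRNA cluster", "scope": "mirna_cluster", "answer": "yes"},
  {"pattern": "(?i)luciferase reporter|binding experiment|binding-site mutagenesis", "scope": "binding_experiments", "answer": "yes"},
  {"pattern": "(?i)luciferase reporter", "scope": "reporter_assay", "answer": "yes"},
  {"pattern": "(?i)qRT-PCR[^.]*decreas", "scope": "mrna_level", "answer": "yes"},
  {"pattern": "(?i)western blot[^.]*protein[^.]*(reduc|decreas)", "scope": "protein_level", "answer": "yes"}
]
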