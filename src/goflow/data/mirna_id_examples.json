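{
  "description": "Normative positive/negative examples for the shipped miRNA identifier patterns. Positives map raw string -> {scheme, prefix, normalized}; negatives must yield no match. Patterns err strict: alias forms without an organism prefix are deliberately not identifiers.",
  "positives": {
    "hsa-miR-21": {"scheme": "mirbase", "prefix": "hsa", "normalized": "hsa-mir-21"},
    "hsa-miR-21-5p": {"scheme": "mirbase", "prefix": "hsa", "normalized": "hsa-mir-21"},
    "hsa-miR-21-3p": {"scheme": "mirbase", "prefix": "hsa", "normalized": "hsa-mir-21"},
    "hsa-mir-21": {"scheme": "mirbase", "prefix": "hsa", "normalized": "hsa-mir-21"},
    "hsa-let-7a": {"scheme": "mirbase", "prefix": "hsa", "normalized": "hsa-let-7a"},
    "hsa-let-7a-1": {"scheme": "mirbase", "prefix": "hsa", "normalized": "hsa-let-7a-1"},
    "mmu-miR-155-5p": {"scheme": "mirbase", "prefix": "mmu", "normalized": "mmu-mir-155"},
    "dre-miR-430a": {"scheme": "mirbase", "prefix": "dre", "normalized": "dre-mir-430a"},
    "cel-lin-4": {"scheme": "mirbase", "prefix": "cel", "normalized": "cel-lin-4"},
    "Hsa-Mir-21": {"scheme": "mirgenedb", "prefix": "Hsa", "normalized": "hsa-mir-21"},
    "Hsa-Mir-21_5p": {"scheme": "mirgenedb", "prefix": "Hsa", "normalized": "hsa-mir-21"},
    "Hsa-Let-7-P1": {"scheme": "mirgenedb", "prefix": "Hsa", "normalized": "hsa-let-7-p1"},
    "Mmu-Mir-155": {"scheme": "mirgenedb", "prefix": "Mmu", "normalized": "mmu-mir-155"}
  },
  "negatives": [
    "microRNAs are small RNAs",
    "miR-21",
    "let-7",
    "miRNA-21",
    "hsa-miR-",
    "XYZhsa-miR-21",
    "the microRNA pathway",
    "pre-miR processing"
  ]
}
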