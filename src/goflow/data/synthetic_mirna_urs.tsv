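normalized_id	urs_taxid
hsa-mir-21	URS00000A2100_9606
hsa-mir-34a	URS00000A34A0_9606
hsa-let-7a	URS00000E07A0_9606
mmu-mir-155	URS00000B1550_10090
rno-mir-122	URS00000C1220_10116
dre-mir-430a	URS00000D430A_7955
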