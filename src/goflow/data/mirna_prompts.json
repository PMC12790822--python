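{
  "binding_experiments": "Does the article describe experiments that probe binding between a microRNA and an mRNA (for example reporter assays, binding-site mutagenesis, or biochemical binding experiments)? Articles that only perform differential expression analysis, in-silico target prediction, or pathway analysis should be answered 'no'.",
  "mirna_cluster": "Is this article a study of a miRNA cluster, where a group of co-transcribed miRNAs acts in concert to exert a regulatory effect? Cluster studies require different treatment and should be answered 'yes' so they can be set aside.",
  "reporter_assay": "Does the paper have a functional interaction between the miRNA and an mRNA, determined by a reporter assay? Acceptable assays include: Luciferase reporter assays where a luciferase reporter gene is fused to the 3'UTR of the target mRNA; and CRISPR/CAS9 deletion of the miRNA response element with subsequent measurement of protein levels.",
  "mrna_level": "Does the paper show that the level of the target mRNA decreases in the presence of the miRNA, measured by qRT-PCR or an equivalent quantitative method (e.g. RNA-seq of the target transcript, northern blot)? A decrease in target mRNA level indicates silencing by mRNA destabilization.",
  "protein_level": "Does the paper show that the level of the target protein decreases in the presence of the miRNA (e.g. by western blot) while the target mRNA level is unchanged? Reduced protein with unchanged mRNA indicates silencing by inhibition of translation."
}
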