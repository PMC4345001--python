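#gtf produced by genemerge
chr1	genemerge	exon	101	200	0.75	+	.	gene_id "GM000001.gene"; transcript_id "GM000001"; support_class "SUPPORTED";
chr1	genemerge	exon	301	400	0.75	+	.	gene_id "GM000001.gene"; transcript_id "GM000001"; support_class "SUPPORTED";
chr1	genemerge	exon	501	600	0.75	+	.	gene_id "GM000001.gene"; transcript_id "GM000001"; support_class "SUPPORTED";
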