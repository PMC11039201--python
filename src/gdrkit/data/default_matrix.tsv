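variant_class	altered gene product level	decreased gene product level	absent gene product	increased gene product level	altered gene product sequence	functionally normal	provenance
transcript_ablation	5	5	5	1	1	1	absent gene product:paper_text;decreased gene product level:paper_text
splice_acceptor_variant	4	4	3	1	4	1	decreased gene product level:paper_text;altered gene product sequence:paper_text
splice_donor_variant	4	4	3	1	4	1	decreased gene product level:paper_text;altered gene product sequence:paper_text
stop_gained|NMD_triggering	5	5	5	1	1	1	decreased gene product level:paper_text;absent gene product:paper_text
stop_gained|NMD_escaping	2	2	1	1	5	1	altered gene product sequence:paper_text
frameshift_variant|NMD_triggering	5	5	5	1	1	1	decreased gene product level:paper_text;absent gene product:paper_text
frameshift_variant|NMD_escaping	2	2	1	1	5	1	altered gene product sequence:paper_text
stop_lost	2	2	1	1	5	1	altered gene product sequence:paper_text
start_lost	4	4	3	1	3	1
inframe_insertion	2	2	1	1	5	1	altered gene product sequence:paper_text
inframe_deletion	2	2	1	1	5	1	altered gene product sequence:paper_text
missense_variant	2	2	2	1	5	2	altered gene product sequence:paper_text
splice_region_variant	3	3	2	1	3	3
synonymous_variant	2	2	1	1	1	5	functionally normal:paper_text
mature_miRNA_variant	3	3	1	1	4	2
5_prime_UTR_variant	4	3	2	3	1	3	decreased gene product level:paper_text
3_prime_UTR_variant	3	3	1	2	1	3	decreased gene product level:paper_text
non_coding_transcript_exon_variant	3	3	1	1	4	2
intron_variant	2	2	1	2	2	4
upstream_gene_variant	3	3	2	3	1	3	altered gene product level:paper_text
TF_binding_site_variant	3	3	1	3	1	3
regulatory_region_variant	3	3	2	3	1	3
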