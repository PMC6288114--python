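annotation	n_snp	genome_percent
3_prime_UTR_variant	56
5_prime_UTR_variant	23
coding_sequence_variant	10
downstream_gene_variant	1200
intergenic_variant	12066	67.32
intron_variant	5775	25.35
missense_variant	180	0.35
non_coding_transcript_variant	9
splice_acceptor_variant	3
splice_donor_variant	3
splice_region_variant	44
stop_gained	3
synonymous_variant	83
upstream_gene_variant	1429
Unknown	33
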