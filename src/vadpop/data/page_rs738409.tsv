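snp_id	chrom	pos	allele_ref	allele_eff	freq_African_American	freq_Asian	freq_Cuban	freq_Dominican	freq_Mexican	freq_Puerto_Rican
rs738409	22	NA	C	G	0.144	0.44	0.28	0.26	0.50	0.34
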