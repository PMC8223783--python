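snp_id	chrom	pos	allele_ref	allele_eff	freq_African	freq_African_American	freq_European	freq_Asian
rs10882272	10	NA	T	C	0.620	0.617	0.383	0.106
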