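snp_id	chrom	pos	allele_ref	allele_eff	freq_Puerto_Rican	freq_Dominican	freq_Cuban	freq_Mexican	freq_Central_American	freq_South_American	freq_Native_American
rs10882272	10	NA	T	C	0.455	0.502	0.410	0.260	0.288	0.278	0.357
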