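group	n	higher_risk_pct	double_risk_pct
Afro-Caribbean	520	40.96	0.96
Non-Hispanic Black	1487	37.93	NA
Mexican	3656	26.39	1.53
Asian	1808	16.76	NA
Non-Hispanic White	1610	16.21	NA
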