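ethnicity	stratum	deficient	sufficient
Non-Hispanic White	total	60	1624
Non-Hispanic White	pregnant	43	349
Non-Hispanic White	pregnant_pir_lt_185	14	101
Non-Hispanic Black	total	128	848
Non-Hispanic Black	pregnant	47	98
Non-Hispanic Black	pregnant_pir_lt_185	33	58
Mexican American	total	72	999
Mexican American	pregnant	36	203
Mexican American	pregnant_pir_lt_185	29	152
Other Hispanic	total	15	153
Other Hispanic	pregnant	10	26
Other Hispanic	pregnant_pir_lt_185	6	16
Other	total	14	169
Other	pregnant	6	43
Other	pregnant_pir_lt_185	2	17
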