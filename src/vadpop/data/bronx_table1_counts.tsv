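ethnicity	deficient	sufficient
Hispanic/Latin American	29	15
Non-Hispanic Black	8	7
Other	3	5
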