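condition	cp_suspect	cp_filler	cp_reject	ca_suspect	ca_filler	ca_reject
seq2	499	124	193	259	161	396
seq5	320	316	166	143	378	281
sim2	433	72	281	204	98	484
sim5	320	172	296	115	232	441
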