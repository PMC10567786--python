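condition	cp_suspect	cp_filler	cp_reject	ca_suspect	ca_filler	ca_reject
seq3	386	205	173	206	241	317
seq6	273	339	174	127	374	285
sim3	371	120	269	139	184	437
sim6	283	191	290	87	249	428
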