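gene	foreground_clade	lnl_H0	lnl_H1
gyrB	HLII	-104105	-101068
pstB	HLII	-39463	-39463
amtB	HLII	-68231	-68232
glnA	HLII	-65896	-65896
glsF	HLII	-249282	-249282
napA	HLII	-23009	-23009
narB	HLII	-38711	-38711
moaA	HLII	-22958	-22958
nirA	HLII	-52348	-52341
gyrB	LLI	-101367	-101356
pstB	LLI	-39407	-39407
amtB	LLI	-68211	-68211
glnA	LLI	-65885	-65885
glsF	LLI	-249371	-249371
napA	LLI	-23014	-23014
narB	LLI	-38790	-38770
moaA	LLI	-22961	-22961
focA	LLI	-17695	-17695
nirA_typeI	LLI	-52349	-52349
nirA_typeII	LLI	-52358	-52358
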