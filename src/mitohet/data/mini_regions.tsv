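name	kind	start	end	strand	frame_start
D-loop	dloop	1851	150	.	.
LC1	low_complexity	60	70	.	.
LC2	low_complexity	1900	1910	.	.
TRNX	tRNA	160	230	H	.
PROT1	protein	301	900	H	301
RRNX	rRNA	950	1100	H	.
PROT2	protein	1200	1700	L	1700
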