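name	kind	start	end	strand	frame_start
D-loop	dloop	16024	576	.	.
LC1	low_complexity	302	316	.	.
LC2	low_complexity	512	526	.	.
LC3	low_complexity	16184	16193	.	.
TRNF	tRNA	577	647	H	.
RNR1	rRNA	648	1601	H	.
TRNV	tRNA	1602	1670	H	.
RNR2	rRNA	1671	3229	H	.
TRNL1	tRNA	3230	3304	H	.
ND1	protein	3307	4262	H	3307
TRNI	tRNA	4263	4331	H	.
TRNQ	tRNA	4329	4400	L	.
TRNM	tRNA	4402	4469	H	.
ND2	protein	4470	5511	H	4470
TRNW	tRNA	5512	5579	H	.
TRNA	tRNA	5587	5655	L	.
TRNN	tRNA	5657	5729	L	.
TRNC	tRNA	5761	5826	L	.
TRNY	tRNA	5826	5891	L	.
CO1	protein	5904	7445	H	5904
TRNS1	tRNA	7446	7514	L	.
TRND	tRNA	7518	7585	H	.
CO2	protein	7586	8269	H	7586
TRNK	tRNA	8295	8364	H	.
ATP8	protein	8366	8572	H	8366
ATP6	protein	8527	9207	H	8527
CO3	protein	9207	9990	H	9207
TRNG	tRNA	9991	10058	H	.
ND3	protein	10059	10404	H	10059
TRNR	tRNA	10405	10469	H	.
ND4L	protein	10470	10766	H	10470
ND4	protein	10760	12137	H	10760
TRNH	tRNA	12138	12206	H	.
TRNS2	tRNA	12207	12265	H	.
TRNL2	tRNA	12266	12336	H	.
ND5	protein	12337	14148	H	12337
ND6	protein	14149	14673	L	14673
TRNE	tRNA	14674	14742	L	.
CYB	protein	14747	15887	H	14747
TRNT	tRNA	15888	15953	H	.
TRNP	tRNA	15956	16023	L	.
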