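entry_name	gx	gy	gz	fav_x	fav_y	fav_z
AK1C3	40.8	0.0	39.1	LCNEC		LCNEC
AK1C1	39.0	0.0	37.4	LCNEC		LCNEC
AL1A1	8.75	2.6e-05	11.8	LCNEC	LCC	LCNEC
CD44	5.56	0.0	5.27	LCNEC		LCNEC
BASP	0.0	32.2	24.1		SCLC	SCLC
SEGN	0.0	21.5	15.9		SCLC	SCLC
MVP	23.8	34.1	0.0	LCC	LCC	
ENOG	0.55	7.23	2.84		SCLC	SCLC
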