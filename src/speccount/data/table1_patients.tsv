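group	patient_no	gender	age	tnm	stage
LCNEC	1	F	68	T1N0M0	IA
LCNEC	2	M	73	T2N0M0	IB
LCNEC	3	M	58	T1N1M0	IIA
LCNEC	4	M	70	T2N0M0	IB
LCNEC	5	M	76	T2N2M0	IIIA
LCNEC	6	M	69	T3N3M0	IIIB
LCNEC	7	M	64	T2N1M0	IIB
LCNEC	8	M	60	T2N2M0	IIIA
LCNEC	9	F	77	T1N0M0	IA
LCNEC	10	M	69	T1N2M0	IIIA
SCLC	1	F	62	T2N0M0	IB
SCLC	2	M	77	T2N1M0	IIB
SCLC	3	M	57	T2N1M0	IIB
SCLC	4	M	76	T1N1M0	IIA
SCLC	5	M	64	T1N1M0	IIA
SCLC	6	F	70	T1N1M0	IIA
SCLC	7	M	69	T1N1M0	IIA
SCLC	8	M	77	T2N0M0	IB
SCLC	9	M	73	T1N0M0	IA
SCLC	10	M	73	T2N1M0	IIB
LCC	1	M	52	T2N1M0	IIB
LCC	2	M	71	T1N0M0	IA
LCC	3	F	57	T1N0M0	IA
LCC	4	M	51	T4N2M0	IIIB
LCC	5	M	72	T1N1M0	IIA
LCC	6	M	67	T1N1M0	IIA
LCC	7	M	67	T2N0M0	IB
LCC	8	M	58	T1N0M0	IA
LCC	9	M	67	T2N0M0	IB
LCC	10	M	66	T1N0M0	IA
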