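family_a	family_b	z_sd	aligned_tms
LysE	RhtB	20.1	5
LysE	CadD	12.1	4
LysE	CaCA2	13.5	3
LysE	MntP	11.8	3
LysE	ILT	12.5	2
LysE	TerC	14.6	3
LysE	NAAT	14.0	5
LysE	NicO	10.8	6
LysE	GAP	12.7	3
LysE	DsbD	12.3	5
LysE	MC	4.1	0
RhtB	CadD	11.9	3
RhtB	CaCA2	13.0	4
RhtB	MntP	13.7	3
RhtB	ILT	13.7	3
RhtB	TerC	13.5	3
RhtB	NAAT	15.0	5
RhtB	NicO	13.8	6
RhtB	GAP	14.5	5
RhtB	DsbD	14.0	5
RhtB	MC	8.8	2
CadD	CaCA2	14.2	3
CadD	MntP	15.7	4
CadD	ILT	13.5	6
CadD	TerC	13.6	4
CadD	NAAT	14.4	5
CadD	NicO	15.1	6
CadD	GAP	12.3	5
CadD	DsbD	11.5	6
CadD	MC	8.5	2
CaCA2	MntP	15.1	3
CaCA2	ILT	15.3	3
CaCA2	TerC	16.2	3
CaCA2	NAAT	12.0	5
CaCA2	NicO	12.5	5
CaCA2	GAP	11.6	5
CaCA2	DsbD	13.2	5
CaCA2	MC	10.5	1
MntP	ILT	12.5	6
MntP	TerC	13.5	5
MntP	NAAT	15.1	4
MntP	NicO	12.3	5
MntP	GAP	11.3	4
MntP	DsbD	16.0	5
MntP	MC	9.1	2
ILT	TerC	13.1	5
ILT	NAAT	11.8	6
ILT	NicO	12.8	6
ILT	GAP	12.8	6
ILT	DsbD	10.9	4
ILT	MC	9.1	1
TerC	NAAT	15.2	3
TerC	NicO	13.9	5
TerC	GAP	12.1	5
TerC	DsbD	12.9	5
TerC	MC	4.4	0
NAAT	NicO	13.5	3
NAAT	GAP	12.8	4
NAAT	DsbD	15.3	6
NAAT	MC	10.0	1
NicO	GAP	12.7	5
NicO	DsbD	14.8	5
NicO	MC	9.3	1
GAP	DsbD	13.1	5
GAP	MC	5.8	2
DsbD	MC	9.9	1
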