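family_x	family_y	protein_a	protein_b	protein_c	protein_d	score_ab	score_bc	score_cd	score_ad	aligned_tms_bc
LysE	RhtB	P94633	H3RH39	Q2SUV5	P76249	32.5	20.1	52.0	9.0	5
LysE	CadD	P64711	K0HW07	K9TWQ5	Q45153	37.0	12.1	36.1	0.7	4
RhtB	CadD	P76249	G9Y0F1	G9WHF3	O05469	72.0	11.9	36.0	1.1	3
LysE	CaCA2	P94633	E0MXD6	C1MR94	P52876	63.0	13.5	31.7	1.6	3
RhtB	CaCA2	P76249	G9Y0F1	K9ULS7	P52876	73.0	13.0	62.4	1.3	4
CadD	CaCA2	O05469	L2SR21	B7FUM2	P52876	50.7	14.2	57.2	2.0	3
RhtB	MntP	P76249	C4GM93	D9SW99	O27840	45.9	13.7	37.5	1.9	3
CadD	MntP	O05469	H3NKZ1	Q727E5	O27840	48.0	15.7	34.3	1.0	4
CaCA2	MntP	P52876	E0UDP4	C0DV56	P76264	74.5	15.1	57.3	1.3	3
RhtB	ILT	P0AG34	A1RAR9	Q2NBF8	Q58AJ4	50.5	13.7	125.9	0.4	3
CadD	ILT	O05469	C2D135	G5JVH6	Q5HSD5	43.1	13.5	41.0	4.2	6
CaCA2	ILT	P52876	F0Y333	Q97V64	Q4J7V8	52.7	15.3	67.2	5.3	3
LysE	TerC	P94633	D7GFT1	Q20ZD5	I3XAB3	40.8	14.6	72.7	-0.2	3
RhtB	TerC	P76249	K8W4X6	WP_010022951	B5UIP4	63.3	13.5	54.9	1.4	3
CadD	TerC	O05469	WP_010652183	G8LRD3	B5UIP4	46.0	13.6	38.5	3.9	4
CaCA2	TerC	P52876	B7FUM2	D7V5X7	B5UIP4	57.2	16.2	62.9	1.3	3
MntP	TerC	P76264	E7S0L5	A2TWJ9	Q7UHX7	43.9	13.5	40.3	2.6	5
ILT	TerC	Q58AJ4	G6EJJ4	Q8KAT3	B5UIP4	125.3	13.1	37.6	0.7	5
LysE	NAAT	P11667	G8QX72	Q2C9W5	O32244	35.1	14.0	40.6	3.9	5
RhtB	NAAT	P0AG38	L7BNM7	H1S8A2	Q8J305	95.4	15.0	39.2	5.2	5
CadD	NAAT	Q45153	K6U069	E3T754	Q8J305	27.1	14.4	40.4	-0.1	5
MntP	NAAT	O27840	A6VQU4	WP_018748573	P67143	20.7	15.1	46.8	2.6	4
TerC	NAAT	I3XAB3	Q5L1S7	T2GCR6	P67143	26.2	15.2	45.5	3.0	3
RhtB	NicO	P0AG38	N9DHM2	G2TLK3	F8C138	68.9	13.8	34.5	1.2	6
CadD	NicO	Q45153	K9ZC80	K6XDF4	F8C138	24.8	15.1	22.4	0.2	6
TerC	NicO	I3XAB3	F4QZA6	M1YUV4	F8C138	55.7	13.9	32.8	1.4	5
NAAT	NicO	Q8J305	H1L1H6	WP_022692950	P76425	38.4	13.5	34.9	0.8	3
RhtB	GAP	P76249	F3KVR3	WP_019358971	K6W6C5	45.2	14.5	16.6	1.7	5
RhtB	DsbD	P0AG38	M4RA58	R1CD96	P45706	35.6	14.0	43.5	-0.2	5
CaCA2	DsbD	B9MIH1	D1JG69	F9DXY9	P45706	23.2	13.2	77.7	-0.5	5
MntP	DsbD	E4RIT5	F7ZP38	F5SD76	P45706	28.2	16.0	70.7	0.6	5
NAAT	DsbD	Q8J305	Q8U2T5	K0NNX9	P45706	82.4	15.3	41.9	2.5	6
NicO	DsbD	B2JAZ6	K9Z039	M1ZHA3	P45706	34.2	14.8	43.2	0.2	5
GAP	DsbD	K6W6C5	WP_018161757	C6D6Q6	Q939U6	31.7	13.1	41.8	1.0	5
LysE	MC	P94633	G8QX72	XP_395934	P12235	35.7	4.1	162.4	0.7	0
RhtB	MC	P76249	F3KVR3	I3WBB4	P12235	43.0	8.8	157.0	1.0	2
CadD	MC	O05469	D2AZ49	XP_003796317	P12235	30.8	8.5	200.7	1.6	2
CaCA2	MC	G0PPC8	L7L942	Q4PMB2	P12235	17.5	10.5	158.1	0.7	1
MntP	MC	O27840	L7VM13	S7NPK9	P12235	35.2	9.1	153.6	-1.0	2
ILT	MC	Q5HSD5	L0W8N6	V9KQ68	P12235	48.2	9.1	149.5	-1.4	1
TerC	MC	I3XAB3	K9CUK2	Q91336	P12235	48.9	4.4	172.4	0.4	0
NAAT	MC	Q8J305	F9RL32	Q91336	P12235	42.7	10.0	176.1	0.6	1
NicO	MC	F8C138	G9QNI4	S9XZZ3	P12235	33.1	9.3	171.4	-0.3	1
GAP	MC	K6W6C5	WP_019971730	V9KQ68	P12235	10.1	5.8	155.4	-0.6	2
DsbD	MC	P45706	B3E4Q5	XP_007059219	P12235	48.4	9.9	159.0	-0.8	1
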