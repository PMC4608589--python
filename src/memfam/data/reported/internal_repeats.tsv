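family	accession	n_tms	tms_first	tms_second	z_sd
CaCA2	Q2JWH3	6	1-3	4-6	13.5
CaCA2	I7M883	6	1-3	4-6	11.3
CaCA2	K4DX00	6	1-3	4-6	5.7
ILT	Q8YX33	7	1-3	4-6	10.7
ILT	K9Q6B8	7	1-3	4-6	9.4
ILT	J2KV33	7	1-3	4-6	8.0
MntP	A8SU47	6	1-3	4-6	8.1
MntP	R9SLI6	6	1-3	4-6	7.4
MntP	C6JCY1	6	1-3	4-6	6.9
TerC	A4IKQ1	7	1-3	4-6	9.4
TerC	G8M4S7	7	1-3	4-6	9.1
TerC	R9LI44	7	1-3	4-6	7.8
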