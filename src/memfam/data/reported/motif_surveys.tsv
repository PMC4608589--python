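families	tms_index	n_displaying	n_total	per_family	motif
CaCA2 & ILT	3	80	80	40 ILT, 40 CaCA2	FGX(K/R)XL
CadD & MntP	4	170	170	85 CadD, 85 MntP	D
CadD & MntP	6	170	170	85 CadD, 85 MntP	G
CadD & MntP	1	170	170	85 CadD, 85 MntP	D
TerC & LysE	3	248	248	124 LysE, 124 TerC	GXXXL
TerC & RhtB	3	176	176	88 TerC, 88 RhtB	GXXYL
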