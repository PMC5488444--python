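taxon	apc	aaap	total	life_history	clade
D_vitifoliae	11	12	23	galling	ingroup
P_caryaecaulis	10	16	26	galling	ingroup
P_caryaemagna	10	15	25	galling	ingroup
P_subelliptica	10	12	22	galling	ingroup
P_caryaevenae	8	12	20	galling	ingroup
P_foveola	7	14	21	galling	ingroup
P_foveata	13	17	30	galling	ingroup
P_caryaefallax	9	14	23	galling	ingroup
P_quercus	19	24	43	free_living	ingroup
A_pisum	18	21	39	free_living	ingroup
M_persicae	16	20	36	free_living	ingroup
P_obesinymphae	11	14	25	galling	ingroup
P_populicaulis	12	18	30	galling	ingroup
T_coweni	12	16	28	galling	ingroup
T_inquilinus	10	17	27	inquiline	ingroup
P_citri	10	28	38	free_living	outgroup
B_tabaci	12	24	36	free_living	outgroup
B_cockerelli	10	25	35	free_living	outgroup
D_melanogaster	10	15	25	free_living	outgroup
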