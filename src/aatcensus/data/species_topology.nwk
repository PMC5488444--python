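((((((((((P_caryaecaulis:1,P_caryaemagna:1):1,P_subelliptica:1):1,P_caryaevenae:1):1,((P_foveola:1,P_foveata:1):1,P_caryaefallax:1):1):1,(D_vitifoliae:1,P_quercus:1):1):1,(((A_pisum:1,M_persicae:1):1,(P_obesinymphae:1,P_populicaulis:1):1):1,(T_coweni:1,T_inquilinus:1):1):1):1,B_cockerelli:1):1,B_tabaci:1):1,P_citri:1):1,D_melanogaster:1);
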