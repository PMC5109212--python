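rsid	effect_allele	other_allele	eaf	beta	se	pval	n	n_cases	n_controls	locus
rs6265	C	T	0.18	0.04	0.01	2.69e-6	129788	NA	NA	11p13 (BDNF)
rs17685	A	G	0.30	0.07	0.01	4.26e-11	129788	NA	NA	7q11.23 (POR)
rs1260326	C	T	0.36	0.04	0.01	7.14e-8	129788	NA	NA	2p24 (GCKR)
rs1481012	A	G	0.89	0.06	0.01	8.93e-8	129788	NA	NA	4q22 (ABCG2)
rs2470893	T	C	0.32	0.12	0.01	2.72e-19	129788	NA	NA	15q24 (CYP1A1)
rs2472297	T	C	0.26	0.14	0.01	2.47e-24	129788	NA	NA	15q24 (CYP1A2)
rs4410790	C	T	0.35	0.10	0.01	3.08e-17	129788	NA	NA	7p21 (AHR)
rs6968554	G	A	0.39	0.10	0.01	5.23e-17	129788	NA	NA	7p21 (AHR)
rs7800944	C	T	0.72	0.05	0.01	2.29e-11	129788	NA	NA	7q11.23 (MLXIPL)
rs9902453	G	A	0.53	0.03	0.01	2.44e-8	129788	NA	NA	17q11.2 (EFCAB5)
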