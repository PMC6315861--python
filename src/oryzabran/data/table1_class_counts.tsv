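chemical_class	Basmati 217	Basmati 370	Gambiaka	Shwetasoke	DM-16	Khao Gaew	Dorado	Sawa Mahsuli	Chennula	Njavara	Calrose	RBT 300	Jasmine 85	IAC 600	LTH	SHZ-2	Rang Jey
amino acids	119	117	120	117	115	99	117	117	105	99	119	122	110	113	119	117	108
carbohydrates	51	52	53	53	52	50	51	50	51	50	48	49	50	53	53	50	51
cofactors & vitamins	27	27	27	27	26	24	27	27	27	26	27	23	27	27	27	26	27
lipids	166	165	165	166	159	164	161	155	155	151	165	161	146	163	165	150	156
nucleotides	37	38	35	35	34	29	37	38	30	29	35	33	37	36	35	36	36
peptides	0	2	11	11	11	7	3	11	1	1	11	1	11	10	8	11	2
secondary metabolites	19	21	19	19	20	19	16	20	19	22	16	17	17	20	22	17	21
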