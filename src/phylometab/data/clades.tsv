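# Per-clade counts of complete glycine/serine synthesis pathway calls for the
# deep-branching bacterial clades (12 rows; 359 strains in total).
clade	n_strains	Glx	Ox	Red	Red-2	GlyC	FDH
Aquificae	7	0	0	0	3	3	5
Thermotogae	11	0	0	11	0	11	1
Bacilli-Bacillales	90	1	13	71	18	89	66
Bacilli-Lactobacillales	90	0	16	0	0	0	5
Clostridia	77	6	6	37	1	39	27
Deinococcus-Thermus	9	0	0	2	6	8	5
Chloroflexi	14	0	2	8	0	8	9
Chlorobi	11	0	0	0	9	11	2
Planctomycetes	4	1	1	1	3	4	2
Nitrospirae	2	0	0	1	0	1	2
Verrucomicrobia	4	1	1	4	0	4	3
Cyanobacteria	40	22	1	0	38	39	4
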