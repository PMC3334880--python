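# Synthetic exemplar gene profiles for the glycine/serine pathway reactions,
# reconstructed from described full-profile organisms (three 8-reaction autotrophic
# profiles and three 7-reaction profiles lacking only reaction 2). These rows are
# illustrative fixtures, not database exports.
strain	clade	1	2	2A	3	4	5	6	7	8	9	10	11	12
MTA	Euryarchaeota	1	1	0	1	1	1	1	1	1	0	0	0	0
CAG	Clostridia	1	1	0	1	1	1	1	1	1	0	0	0	0
NDE	Nitrospirae	1	1	0	1	1	1	1	1	1	0	0	0	0
AAE	Aquificae	1	0	1	1	1	1	1	1	1	0	0	0	0
CCH	Chlorobi	1	0	1	1	1	1	1	1	1	0	0	0	0
NPU	Cyanobacteria	1	0	1	1	1	1	1	1	1	0	0	0	0
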