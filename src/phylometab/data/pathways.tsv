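# Glycine/serine pathway-call definitions. The Red and Red(-2) calls combine the
# autotrophic (from CO2) and heterotrophic (from formate) forms, so reaction 1 is not
# required for the call and is counted separately under FDH; step_reactions lists the
# autotrophic form used for enzymatic step counting.
id	required_present	required_absent	step_reactions
Glx	12		12
Ox	9,10,11		9,10,11
Red	2,3,4,5,6,7,8		1,2,3,4,5,6,7,8
Red-2	3,4,5,6,7,8	2	1,3,4,5,6,7,8
GlyC	5,6,7,8		5,6,7,8
FDH	1		1
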