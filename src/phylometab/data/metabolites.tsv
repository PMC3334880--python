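# Metabolite table. formula uses element-count tokens; Thf/Mpt/Lip/Coa are conserved
# carrier pseudo-elements (moiety bookkeeping); atp carries the transferred phosphoryl
# (HO3P) and red one H2 equivalent so that C/N/O/P balance is exact network-wide.
id	name	formula	is_precursor	is_exchangeable	carrier_free
co2	carbon dioxide	CO2	0	1	0
hco3	bicarbonate	CH2O3	0	1	0
co	carbon monoxide	CO	0	1	0
formate	formate	CH2O2	0	1	0
formate_w	formate (discharged surplus C1, waste only)	CH2O2	0	1	0
nh3	ammonia	H3N	0	1	0
h2o	water	H2O	0	1	0
pi	inorganic phosphate	H3PO4	0	1	0
atp	ATP hydrolysis unit (phosphoryl)	HO3P	0	1	0
red	reductant (H2 equivalent)	H2	0	1	0
thf	tetrahydrofolate	Thf	0	0	1
formyl_thf	10-formyl-THF	ThfCHO	0	0	0
formyl5_thf	5-formyl-THF	ThfCHO	0	0	0
methenyl_thf	5,10-methenyl-THF	ThfCH	0	0	0
methylene_thf	5,10-methylene-THF	ThfCH2	0	0	0
methyl_thf	5-methyl-THF	ThfCH3	0	0	0
h4mpt	tetrahydromethanopterin	Mpt	0	0	1
formyl_h4mpt	formyl-H4MPT	MptCHO	0	0	0
methenyl_h4mpt	methenyl-H4MPT	MptCH	0	0	0
methylene_h4mpt	methylene-H4MPT	MptCH2	0	0	0
methyl_h4mpt	methyl-H4MPT	MptCH3	0	0	0
lip	lipoamide (oxidized)	Lip	0	0	1
dihydrolip	dihydrolipoamide	LipH2	0	0	0
aminomethyl_lip	S-aminomethyl-dihydrolipoamide	LipCH4N	0	0	0
coa	coenzyme A	Coa	0	0	1
acetyl_coa	acetyl-CoA	CoaC2H3O	1	0	0
succinyl_coa	succinyl-CoA	CoaC4H5O3	1	0	0
citryl_coa	citryl-CoA	CoaC6H7O6	0	0	0
malonyl_coa	malonyl-CoA	CoaC3H3O3	0	0	0
propionyl_coa	propionyl-CoA	CoaC3H5O	0	0	0
methylmalonyl_coa	methylmalonyl-CoA	CoaC4H5O3	0	0	0
malyl_coa	L-malyl-CoA	CoaC4H5O4	0	0	0
pyruvate	pyruvate	C3H4O3	1	0	0
oaa	oxaloacetate	C4H4O5	1	0	0
akg	alpha-ketoglutarate	C5H6O5	1	0	0
glu	glutamate	C5H9NO4	0	0	0
malate	malate	C4H6O5	0	0	0
fumarate	fumarate	C4H4O4	0	0	0
succinate	succinate	C4H6O4	0	0	0
isocitrate	isocitrate	C6H8O7	0	0	0
citrate	citrate	C6H8O7	0	0	0
glx	glyoxylate	C2H2O3	0	0	0
glycine	glycine	C2H5NO2	0	0	0
serine	L-serine	C3H7NO3	0	0	0
pser	O-phosphoserine	C3H8NO6P	0	0	0
php	3-phosphohydroxypyruvate	C3H5O7P	0	0	0
pg3	3-phosphoglycerate	C3H7O7P	0	0	0
pg2	2-phosphoglycerate	C3H7O7P	0	0	0
pep	phosphoenolpyruvate	C3H5O6P	0	0	0
ru5p	ribulose-5-phosphate	C5H11O8P	0	0	0
rubp	ribulose-1,5-bisphosphate	C5H12O11P2	0	0	0
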