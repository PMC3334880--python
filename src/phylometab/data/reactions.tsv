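# Reaction table. Numbered ids 1-12 plus 2A are the folate one-carbon / glycine-serine
# reactions; the rest carry short mnemonic ids. Directions as written are the reductive /
# biosynthetic directions; reversible=1 allows the reverse. ATP-coupled activations are
# written irreversible (forward) so ATP is never recovered by running them backwards;
# succinyl-CoA synthetase (scs) is the deliberate exception (substrate-level
# phosphorylation is freely reversible). carbon_species flags the inorganic carbon
# species a reaction takes up.
id	name	ec	equation	reversible	o2_sensitive	carbon_species	module
1	formate dehydrogenase (CO2 reductase)	1.2.1.2	1 co2 + 1 red -> 1 formate	0	0	CO2	fdh
2	10-formyl-THF synthase	6.3.4.3	1 formate + 1 thf + 1 atp -> 1 formyl_thf + 1 pi	0	0	formate	thf_c1
2A	5-formyl-THF cycloligase	6.3.3.2	1 formyl5_thf + 1 atp -> 1 methenyl_thf + 1 pi	0	0	none	thf_c1
3	methenyl-THF cyclohydrolase	3.5.4.9	1 formyl_thf -> 1 methenyl_thf + 1 h2o	1	0	none	thf_c1
4	methylene-THF dehydrogenase	1.5.1.5	1 methenyl_thf + 1 red -> 1 methylene_thf	1	0	none	thf_c1
5	dihydrolipoamide dehydrogenase (GCS L)	1.8.1.4	1 lip + 1 red -> 1 dihydrolip	1	0	none	gcs
6	aminomethyltransferase (GCS T)	2.1.2.10	1 methylene_thf + 1 nh3 + 1 dihydrolip -> 1 aminomethyl_lip + 1 thf	1	0	none	gcs
7	glycine dehydrogenase (GCS P)	1.4.4.2	1 aminomethyl_lip + 1 co2 -> 1 glycine + 1 lip	1	0	CO2	gcs
8	serine hydroxymethyltransferase	2.1.2.1	1 glycine + 1 methylene_thf + 1 h2o -> 1 serine + 1 thf	1	0	none	shmt
9	phosphoserine phosphatase	3.1.3.3	1 pser + 1 h2o -> 1 serine + 1 pi	0	0	none	ox_serine
10	phosphoserine aminotransferase	2.6.1.52	1 php + 1 glu -> 1 pser + 1 akg	1	0	none	ox_serine
11	3-phosphoglycerate dehydrogenase	1.1.1.95	1 pg3 -> 1 php + 1 red	1	0	none	ox_serine
12	alanine-glyoxylate transaminase	2.6.1.44	1 glx + 1 glu -> 1 glycine + 1 akg	1	0	none	glyox
mtr	methylene-THF reductase	1.5.1.20	1 methylene_thf + 1 red -> 1 methyl_thf	0	0	none	methyl_branch
codh	CO dehydrogenase	1.2.7.4	1 co2 + 1 red -> 1 co + 1 h2o	1	1	CO2	acs
acs	acetyl-CoA synthase	2.3.1.169	1 methyl_thf + 1 co + 1 coa -> 1 acetyl_coa + 1 thf	0	1	CO	acs
pfor	pyruvate:ferredoxin oxidoreductase	1.2.7.1	1 acetyl_coa + 1 co2 + 1 red -> 1 pyruvate + 1 coa	1	0	CO2	pyr_bridge
pyc	pyruvate carboxylase (CO2 form)	6.4.1.1	1 pyruvate + 1 co2 + 1 atp + 1 h2o -> 1 oaa + 1 pi	0	0	CO2	pyc
pyc_hco3	pyruvate carboxylase (bicarbonate form)	6.4.1.1	1 pyruvate + 1 hco3 + 1 atp -> 1 oaa + 1 pi	0	0	HCO3	pyc_hco3
mdh	malate dehydrogenase	1.1.1.37	1 oaa + 1 red -> 1 malate	1	0	none	rtca_arc1
fum	fumarase	4.2.1.2	1 malate -> 1 fumarate + 1 h2o	1	0	none	rtca_arc1
frd	fumarate reductase	1.3.1.6	1 fumarate + 1 red -> 1 succinate	1	0	none	rtca_arc1
scs	succinyl-CoA synthetase	6.2.1.5	1 succinate + 1 coa + 1 atp -> 1 succinyl_coa + 1 pi	1	0	none	scs
ogor	2-oxoglutarate:ferredoxin oxidoreductase	1.2.7.3	1 succinyl_coa + 1 co2 + 1 red -> 1 akg + 1 coa	1	0	CO2	rtca_arc2
icdh	isocitrate dehydrogenase (carboxylating)	1.1.1.41	1 akg + 1 co2 + 1 red -> 1 isocitrate	1	0	CO2	rtca_arc2
aco	aconitase	4.2.1.3	1 isocitrate -> 1 citrate	1	0	none	rtca_arc2
ccs	citryl-CoA synthetase	6.2.1.18	1 citrate + 1 coa + 1 atp -> 1 citryl_coa + 1 pi	0	0	none	ccs
ccl	citryl-CoA lyase	4.1.3.34	1 citryl_coa -> 1 acetyl_coa + 1 oaa	0	0	none	ccs
gdh	glutamate dehydrogenase	1.4.1.2	1 akg + 1 nh3 + 1 red -> 1 glu + 1 h2o	1	0	none	amino_shuttle
fthfh	10-formyl-THF hydrolase	3.5.1.10	1 formyl_thf + 1 h2o -> 1 formate + 1 thf	0	0	none	c1_discharge
ppdk	pyruvate,phosphate dikinase	2.7.9.1	1 pyruvate + 1 atp -> 1 pep	1	0	none	gluconeo
eno	enolase	4.2.1.11	1 pep + 1 h2o -> 1 pg2	1	0	none	gluconeo
pgm	phosphoglycerate mutase	5.4.2.11	1 pg2 -> 1 pg3	1	0	none	gluconeo
rbc	ribulose-bisphosphate carboxylase	4.1.1.39	1 rubp + 1 co2 + 1 h2o -> 2 pg3	0	0	CO2	cbb
prk	phosphoribulokinase	2.7.1.19	1 ru5p + 1 atp -> 1 rubp	0	0	none	cbb
cbbr	pentose regeneration (lumped)		5 pg3 + 5 atp + 5 red + 2 h2o -> 3 ru5p + 7 pi	0	0	none	cbb
accase	acetyl-CoA carboxylase	6.4.1.2	1 acetyl_coa + 1 hco3 + 1 atp -> 1 malonyl_coa + 1 pi	0	0	HCO3	hp3_arc
mcr	malonyl-CoA to propionyl-CoA (lumped)		1 malonyl_coa + 3 red + 1 atp -> 1 propionyl_coa + 1 h2o + 1 pi	0	0	none	hp3_arc
pcc	propionyl-CoA carboxylase	6.4.1.3	1 propionyl_coa + 1 hco3 + 1 atp -> 1 methylmalonyl_coa + 1 pi	0	0	HCO3	hp3_arc
mcm	methylmalonyl-CoA mutase	5.4.99.2	1 methylmalonyl_coa -> 1 succinyl_coa	1	0	none	hp3_arc
hb4	4-hydroxybutyrate arc (lumped)		1 succinyl_coa + 1 coa + 1 red + 1 atp -> 2 acetyl_coa + 1 pi	0	0	none	hb4_arc
icl	isocitrate lyase	4.1.3.1	1 isocitrate -> 1 succinate + 1 glx	1	0	none	glyox
mtk	malate-CoA ligase	6.2.1.9	1 malate + 1 coa + 1 atp -> 1 malyl_coa + 1 pi	0	0	none	hp3_glyox
mcl	malyl-CoA lyase	4.1.3.24	1 malyl_coa -> 1 acetyl_coa + 1 glx	1	0	none	hp3_glyox
mml	glyoxylate-propionyl-CoA assimilation (lumped)		1 glx + 1 propionyl_coa -> 1 pyruvate + 1 acetyl_coa	0	0	none	hp3_glyox
fmd	formyl-H4MPT synthesis (lumped, ATP-free)		1 co2 + 1 red + 1 h4mpt -> 1 formyl_h4mpt + 1 h2o	0	0	CO2	h4mpt_c1
mch	methenyl-H4MPT cyclohydrolase	3.5.4.27	1 formyl_h4mpt -> 1 methenyl_h4mpt + 1 h2o	1	0	none	h4mpt_c1
mtd	methylene-H4MPT dehydrogenase	1.5.98.1	1 methenyl_h4mpt + 1 red -> 1 methylene_h4mpt	1	0	none	h4mpt_c1
mer	methylene-H4MPT reductase	1.5.98.2	1 methylene_h4mpt + 1 red -> 1 methyl_h4mpt	0	0	none	h4mpt_c1
acsm	acetyl-CoA synthase (H4MPT methyl donor)	2.3.1.169	1 methyl_h4mpt + 1 co + 1 coa -> 1 acetyl_coa + 1 h4mpt	0	1	CO	acs_m
fhhm	formyl-H4MPT hydrolase	3.5.1.10	1 formyl_h4mpt + 1 h2o -> 1 formate + 1 h4mpt	0	0	none	c1_discharge_m
shmtm	serine hydroxymethyltransferase (H4MPT)	2.1.2.1	1 glycine + 1 methylene_h4mpt + 1 h2o -> 1 serine + 1 h4mpt	1	0	none	shmt_m
shmtox	serine cleavage, surplus C1 discharged as formate (convention)		1 serine + 1 h2o -> 1 glycine + 1 formate_w + 1 red	0	0	none	c1_waste
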