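# Carbon-fixation phenotype definitions. A phenotype is a set of named reaction modules
# plus an environment. latent_modules are modules carried in the gene complement (they
# count for edit distance) but not wired into the active metabolic network (excluded
# from viability witnesses and channel-redundancy counting). observed=0 marks
# hypothesized nodes and costing contexts. ctx_* phenotypes are the biosynthetic-cost
# contexts for the glycine/serine cost table.
id	name	modules	extra_reactions	latent_modules	env_o2	env_carbon	env_reductant	env_atp	observed	observed_in
linked_rtca_wl	linked rTCA-WL root network	fdh,thf_c1,gcs,shmt,pyr_bridge,pyc,gluconeo,amino_shuttle,methyl_branch,acs,rtca_arc1,scs,rtca_arc2,ccs			0	CO2	1	1	0	hypothesized root phenotype
rtca_hybrid	rTCA with incomplete WL glycine/serine branch	fdh,thf_c1,gcs,shmt,pyr_bridge,pyc,gluconeo,amino_shuttle,methyl_branch,rtca_arc1,scs,rtca_arc2,ccs			0	CO2	1	1	1	Aquificales; Nitrospirae
wl_acetogen	Wood-Ljungdahl with incomplete rTCA	fdh,thf_c1,gcs,shmt,pyr_bridge,pyc,gluconeo,amino_shuttle,methyl_branch,acs,rtca_arc1,scs,rtca_arc2			0	CO2	1	1	1	acetogenic Firmicutes (Clostridia)
wl_4hb	Wood-Ljungdahl carrying latent 4HB arc	fdh,thf_c1,gcs,shmt,pyr_bridge,pyc,gluconeo,amino_shuttle,methyl_branch,acs,rtca_arc1,scs,rtca_arc2,hb4_arc		hb4_arc	0	CO2	1	1	1	Clostridia (C. kluyveri-like)
dc_4hb	dicarboxylate/4-hydroxybutyrate cycle	fdh,thf_c1,gcs,shmt,pyr_bridge,pyc,gluconeo,amino_shuttle,methyl_branch,rtca_arc1,scs,rtca_arc2,hb4_arc			0	CO2	1	1	1	Thermoproteales (Crenarchaeota)
hp_4hb	3-hydroxypropionate/4-hydroxybutyrate cycle	fdh,thf_c1,gcs,shmt,pyr_bridge,pyc,gluconeo,amino_shuttle,methyl_branch,rtca_arc1,scs,rtca_arc2,hb4_arc,hp3_arc			0	CO2|HCO3	1	1	1	Sulfolobales (Crenarchaeota)
cbb_lineage	rTCA lineage with CBB cycle	fdh,thf_c1,gcs,shmt,pyr_bridge,pyc,gluconeo,amino_shuttle,methyl_branch,rtca_arc1,scs,rtca_arc2,ccs,cbb			1	CO2	1	1	1	early CBB-bearing bacteria
cbb_glyox	CBB lineage with glyoxylate glycine route	fdh,thf_c1,gcs,shmt,pyr_bridge,pyc,gluconeo,amino_shuttle,methyl_branch,rtca_arc1,scs,rtca_arc2,ccs,cbb,glyox			1	CO2	1	1	1	Cyanobacteria
hp_bicycle	3-hydroxypropionate bicycle	fdh,thf_c1,gcs,shmt,pyr_bridge,pyc,gluconeo,amino_shuttle,rtca_arc1,scs,rtca_arc2,hp3_arc,hp3_glyox			0	CO2|HCO3	1	1	1	Chloroflexi
ctx_red_thf	reductive THF glycine/serine context	fdh,thf_c1,gcs,shmt			0	CO2	1	1	0	costing context (Red row)
ctx_ox_rtca	oxidative serine route in rTCA autotroph	rtca_arc1,scs,rtca_arc2,ccs,pyr_bridge,pyc,gluconeo,ox_serine,amino_shuttle,shmt,thf_c1,c1_discharge			0	CO2	1	1	0	costing context (Ox in rTCA row)
ctx_ox_wl_thf	oxidative serine route in WL (THF) autotroph	fdh,thf_c1,methyl_branch,acs,pyr_bridge,pyc,gluconeo,ox_serine,amino_shuttle,c1_waste,rtca_arc1,scs,rtca_arc2			0	CO2	1	1	0	costing context (Ox in WL [THF] row)
ctx_ox_wl_h4mpt	oxidative serine route in WL (H4MPT) autotroph	h4mpt_c1,acs,acs_m,pyr_bridge,pyc,gluconeo,ox_serine,amino_shuttle,c1_waste,rtca_arc1,scs,rtca_arc2			0	CO2	1	1	0	costing context (Ox in WL [H4MPT] row)
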