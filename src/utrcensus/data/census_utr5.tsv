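hgvs	gene	utr_side	clinvar_class	study_class	mechanism	functional_evidence
NM_000460.3:c.-31G>T	THPO	utr5	P	LP	uorf_existing
NM_000460.3:c.-47del	THPO	utr5	P	LP	uorf_existing
NM_005144.4:c.-218A>G	HR	utr5	P	LP	uorf_existing
NM_005144.4:c.-249C>G	HR	utr5	P	LP	uorf_existing
NM_005144.4:c.-315C>T	HR	utr5	P	LP	uorf_existing
NM_005144.4:c.-320T>C	HR	utr5	P	P	uorf_existing
NM_005144.4:c.-320T>A	HR	utr5	LP	LP	uorf_existing
NM_000280.4:c.-118_-117del	PAX6	utr5	P_and_LP_conflicting	P	uorf_existing
NM_000280.4:c.-122dup	PAX6	utr5	LP	P	uorf_existing
NM_004064.4:c.-454_-451del	CDKN1B	utr5	P	LP	uorf_existing
NM_006516.2:c.-107G>A	SLC2A1	utr5	LP	P	novel_upstream_start
NM_001204.7:c.-947_-946delinsAT	BMPR2	utr5	P	LP	novel_upstream_start
NM_000939.3:c.-11C>A	POMC	utr5	P	LP	novel_upstream_start
NM_000313.3:c.-39C>T	PROS1	utr5	P	LP	novel_upstream_start
NM_054027.5:c.-11C>T	ANKH	utr5	P	LP	novel_upstream_start
NM_001131005.2:c.-8C>T	MEF2C	utr5	P	LP	novel_upstream_start
NM_001131005.2:c.-26C>T	MEF2C	utr5	P	LP	novel_upstream_start
NM_001131005.2:c.-66A>T	MEF2C	utr5	P	LP	novel_upstream_start
NM_001114753.2:c.-127C>T	ENG	utr5	P_and_LP_conflicting	LP	novel_upstream_start
NM_012203.2:c.-4_-3delinsAT	GRHPR	utr5	P	LP	novel_upstream_start
NM_001025295.2:c.-14C>T	IFITM5	utr5	P	P	novel_upstream_start
NM_000518.4:c.-29G>A	HBB	utr5	P	LP	novel_upstream_start
NM_006767.3:c.-38T>A	LZTR1	utr5	P_and_LP_conflicting	LP	novel_upstream_start
NM_002032.2:c.-164A>T	FTH1	utr5	P	LP	mrna_protein_interaction
NM_000146.3:c.-168G>A	FTL	utr5	P	P	mrna_protein_interaction
NM_000146.3:c.-168G>C	FTL	utr5	P	P	mrna_protein_interaction
NM_000146.3:c.-168G>T	FTL	utr5	P	P	mrna_protein_interaction
NM_000146.3:c.-167C>T	FTL	utr5	P	P	mrna_protein_interaction
NM_000146.3:c.-164C>A	FTL	utr5	P	LP	mrna_protein_interaction
NM_000146.3:c.-164C>T	FTL	utr5	P	P	mrna_protein_interaction
NM_000146.3:c.-161C>G	FTL	utr5	P	LP	mrna_protein_interaction
NM_000146.3:c.-161C>T	FTL	utr5	P	P	mrna_protein_interaction
NM_000146.3:c.-160A>G	FTL	utr5	P	LP	mrna_protein_interaction
NM_000146.3:c.-157G>A	FTL	utr5	P	P	mrna_protein_interaction
NM_000146.3:c.-149G>C	FTL	utr5	P	LP	mrna_protein_interaction
NM_003051.3:c.-202G>A	SLC16A1	utr5	P	LP	promoter_activity
NM_005105.4:c.-21G>A	RBM8A	utr5	P_and_LP_conflicting	P	promoter_activity
NM_000551.3:c.-75_-55del	VHL	utr5	LP	LP	promoter_activity
NM_000037.3:c.-73_-72del	ANK1	utr5	P	LP	promoter_activity
NM_000375.2:c.-203T>C	UROS	utr5	P	LP	promoter_activity
NM_014915.2:c.-127A>T	ANKRD26	utr5	P_and_LP_conflicting	P	promoter_activity
NM_014915.2:c.-127A>G	ANKRD26	utr5	P	LP	promoter_activity
NM_014915.2:c.-127A>C	ANKRD26	utr5	LP	LP	promoter_activity
NM_014915.2:c.-128G>A	ANKRD26	utr5	P	P	promoter_activity
NM_000518.4:c.-18C>G	HBB	utr5	P	LP	promoter_activity
NM_001814.5:c.-55C>A	CTSC	utr5	P	LP	promoter_activity
NM_017671.4:c.-20A>G	FERMT1	utr5	P	LP	promoter_activity
NM_000026.3:c.-49T>C	ADSL	utr5	LP	LP	promoter_activity
NM_000133.3:c.-17A>G	F9	utr5	P	LP	promoter_activity
NM_007294.3:c.-107A>T	BRCA1	utr5	P	LP	promoter_methylation
NM_000249.3:c.-27C>A	MLH1	utr5	P_and_LP_conflicting	LP	promoter_methylation
NM_021067.4:c.-60A>G	GINS1	utr5	P	LP	splicing_5utr
NM_021067.4:c.-48C>G	GINS1	utr5	P	P	splicing_5utr
NM_000451.3:c.-19G>A	SHOX	utr5	P_and_LP_conflicting	LP	splicing_5utr
NM_000166.5:c.-17G>A	GJB1	utr5	P_and_LP_conflicting	LP	splicing_5utr
NM_005105.4:c.-19G>A	RBM8A	utr5	P	LP	undetermined
NM_022787.3:c.-69C>T	NMNAT1	utr5	P	LP	undetermined
NM_173546.2:c.-158C>T	KLHDC8B	utr5	P	P	undetermined
NM_133433.4:c.-321_-320delinsA	NIPBL	utr5	P	LP	undetermined
NM_014915.2:c.-126T>G	ANKRD26	utr5	P	LP	undetermined
NM_014915.2:c.-126T>C	ANKRD26	utr5	P_and_LP_conflicting	LP	undetermined
NM_014915.2:c.-128G>T	ANKRD26	utr5	LP	LP	undetermined
NM_014915.2:c.-128G>C	ANKRD26	utr5	LP	LP	undetermined
NM_014915.2:c.-134G>A	ANKRD26	utr5	P_and_LP_conflicting	LP	undetermined
NM_000518.4:c.-50A>C	HBB	utr5	P	LP	undetermined
NM_000133.3:c.-22T>C	F9	utr5	P	LP	undetermined
NM_001551.3:c.-57_-55delinsAA	IGBP1	utr5	P	LP	undetermined
NM_000166.5:c.-103C>T	GJB1	utr5	P	LP	undetermined
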