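hgvs	gene	utr_side	clinvar_class	study_class	mechanism	functional_evidence
NM_000518.4:c.*32A>C	HBB	utr3	P	LP	mirna_binding
NM_001845.5:c.*35C>A	COL4A1	utr3	P	LP	mirna_binding
NM_001845.5:c.*32G>T	COL4A1	utr3	P	P	mirna_binding
NM_001845.5:c.*32G>A	COL4A1	utr3	P	P	mirna_binding
NM_001845.5:c.*31G>T	COL4A1	utr3	P	LP	mirna_binding
NM_001281503.1:c.*689G>A	SLITRK1	utr3	P	P	mirna_binding
NM_006044.3:c.*282A>T	HDAC6	utr3	P	LP	mirna_binding
NM_014017.3:c.*23C>A	LAMTOR2	utr3	P	LP	polyadenylation_signal
NM_000518.4:c.*110_*114del	HBB	utr3	P	LP	polyadenylation_signal
NM_000518.4:c.*113A>G	HBB	utr3	P_and_LP_conflicting	LP	polyadenylation_signal
NM_000518.4:c.*110T>C	HBB	utr3	P	P	polyadenylation_signal
NM_000518.4:c.*110T>A	HBB	utr3	P	LP	polyadenylation_signal
NM_000518.4:c.*93_*105del	HBB	utr3	P	LP	polyadenylation_signal
NM_000517.4:c.*92A>G	HBA2	utr3	P	LP	polyadenylation_signal
NM_000517.4:c.*94A>G	HBA2	utr3	P	P	polyadenylation_signal
NM_003491.3:c.*43A>G	NAA10	utr3	LP	LP	polyadenylation_signal
NM_003491.3:c.*39A>G	NAA10	utr3	P_and_LP_conflicting	LP	polyadenylation_signal
NM_000207.2:c.*59A>G	INS	utr3	P	LP	mrna_stability
NM_003073.4:c.*82C>T	SMARCB1	utr3	P_and_LP_conflicting	LP	mrna_stability
NM_001017980.3:c.*13_*104del	VMA21	utr3	P	LP	mrna_stability
NM_000132.3:c.*56G>T	F8	utr3	LP	LP	splicing_3utr
NM_206926.1:c.*1107T>C	SELENON	utr3	LP	LP	secondary_structure
NM_000210.3:c.*94_*96del	ITGA6	utr3	LP	LP	undetermined
NM_000518.4:c.*6C>G	HBB	utr3	P	P	undetermined
NM_001017980.3:c.*6A>G	VMA21	utr3	P	LP	undetermined
NM_000444.5:c.*231A>G	PHEX	utr3	P_and_LP_conflicting	LP	undetermined
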