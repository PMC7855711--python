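list	lncrna_id
A	DLEU1
A	EP300-AS1
A	HCP5
A	LINC00261
A	LINC00483
A	LINC00675
A	LINC01207
A	MCF2L-AS1
A	TFAP2A-AS1
A	THAP9-AS1
A	TTC28-AS1
A	USP30-AS1
B	LINC00312
B	MEG3
B	RUNX1-IT1
B	TP73-AS1
C	A2M-AS1
C	ADAMTS9-AS2
C	ASAP1-IT1
C	CCDC144NL-AS1
C	CCDC18-AS1
C	DAPK1-IT1
C	DLEU2
C	EGOT
C	HYMAI
C	KLF3-AS1
C	LINC00312
C	LINC00622
C	LINC00623
C	LINC00663
C	LINC00702
C	LINC00865
C	LINC00869
C	LINC00893
C	LINC01138
C	LINC01279
C	LINC01410
C	LINC-PINT
C	MAGI2-AS3
C	MEG3
C	MIR99AHG
C	MLLT4-AS1
C	NR2F1-AS1
C	PSMA3-AS1
C	PSMD5-AS1
C	RUNX1-IT1
C	SERTAD4-AS1
C	STX17-AS1
C	TAPT1-AS1
C	TP53TG1
C	TP73-AS1
C	TUG1
C	ZNF561-AS1
C	ZNF667-AS1
D	DLEU1
D	LINC00261
D	LINC00483
D	TMPO-AS1
D	LINC01207
D	MCF2L-AS1
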