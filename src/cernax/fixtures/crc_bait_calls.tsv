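dataset_id	feature_id	direction
D01	ACOT7	down_in_severe
D01	ATP5B	down_in_severe
D01	AURKAIP1	down_in_severe
D01	CASP1	down_in_severe
D01	CONFLICTG	up_in_severe
D01	CXCL3	down_in_severe
D01	CYP1B1	up_in_severe
D01	FUT4	down_in_severe
D01	GSR	down_in_severe
D01	IDO1	down_in_severe
D01	KIF11	down_in_severe
D01	MCM5	down_in_severe
D01	NONBAIT1	up_in_severe
D01	PIGR	down_in_severe
D01	RANBP1	down_in_severe
D01	SCO2	down_in_severe
D01	TTLL12	down_in_severe
D02	ACOT7	down_in_severe
D02	ATP5B	down_in_severe
D02	AURKAIP1	down_in_severe
D02	CASP1	down_in_severe
D02	CONFLICTG	up_in_severe
D02	CXCL3	down_in_severe
D02	CYP1B1	up_in_severe
D02	FUT4	down_in_severe
D02	GSR	down_in_severe
D02	IDO1	down_in_severe
D02	KIF11	down_in_severe
D02	MCM5	down_in_severe
D02	NONBAIT1	up_in_severe
D02	NPR3	up_in_severe
D02	PIGR	down_in_severe
D02	RANBP1	down_in_severe
D02	SCO2	down_in_severe
D02	TTLL12	down_in_severe
D03	ACOT7	down_in_severe
D03	AURKAIP1	down_in_severe
D03	CASP1	down_in_severe
D03	CONFLICTG	up_in_severe
D03	CYP1B1	up_in_severe
D03	FUT4	down_in_severe
D03	GSR	down_in_severe
D03	KIF11	down_in_severe
D03	MCM5	down_in_severe
D03	NONBAIT1	up_in_severe
D03	NONBAIT2	down_in_severe
D03	NPR3	up_in_severe
D03	RANBP1	down_in_severe
D03	RGL2	up_in_severe
D03	SCO2	down_in_severe
D04	ACOT7	down_in_severe
D04	AGPAT5	down_in_severe
D04	AURKAIP1	down_in_severe
D04	CASP1	down_in_severe
D04	CEP55	down_in_severe
D04	CONFLICTG	up_in_severe
D04	CYP1B1	up_in_severe
D04	FUT4	down_in_severe
D04	GSR	down_in_severe
D04	HNRNPAB	down_in_severe
D04	KIF11	down_in_severe
D04	MCM5	down_in_severe
D04	NONBAIT1	up_in_severe
D04	NONBAIT2	down_in_severe
D04	NPR3	up_in_severe
D04	PBK	down_in_severe
D04	RANBP1	down_in_severe
D04	RGL2	up_in_severe
D04	SCO2	down_in_severe
D04	SLIT2	up_in_severe
D04	TOE1	down_in_severe
D05	ACOT7	down_in_severe
D05	AGPAT5	down_in_severe
D05	AURKAIP1	down_in_severe
D05	CASP1	down_in_severe
D05	CEP55	down_in_severe
D05	CONFLICTG	up_in_severe
D05	CYP1B1	up_in_severe
D05	FUT4	down_in_severe
D05	GSR	down_in_severe
D05	HNRNPAB	down_in_severe
D05	KIF11	down_in_severe
D05	MCM5	down_in_severe
D05	NONBAIT1	up_in_severe
D05	NONBAIT2	down_in_severe
D05	NPR3	up_in_severe
D05	PBK	down_in_severe
D05	RANBP1	down_in_severe
D05	RGL2	up_in_severe
D05	SCO2	down_in_severe
D05	SLIT2	up_in_severe
D05	TOE1	down_in_severe
D05	TSPAN2	up_in_severe
D06	ACOT7	down_in_severe
D06	AGPAT5	down_in_severe
D06	AURKAIP1	down_in_severe
D06	CASP1	down_in_severe
D06	CEP55	down_in_severe
D06	CONFLICTG	up_in_severe
D06	CYP1B1	up_in_severe
D06	FUT4	down_in_severe
D06	GSR	down_in_severe
D06	HNRNPAB	down_in_severe
D06	KIF11	down_in_severe
D06	MCM5	down_in_severe
D06	NONBAIT2	down_in_severe
D06	NPR3	up_in_severe
D06	PBK	down_in_severe
D06	RANBP1	down_in_severe
D06	RGL2	up_in_severe
D06	SCO2	down_in_severe
D06	SLIT2	up_in_severe
D06	TOE1	down_in_severe
D06	TSPAN2	up_in_severe
D07	AGPAT5	down_in_severe
D07	ATP5B	down_in_severe
D07	CEP55	down_in_severe
D07	CONFLICTG	down_in_severe
D07	CXCL3	down_in_severe
D07	CYP1B1	up_in_severe
D07	HNRNPAB	down_in_severe
D07	IDO1	down_in_severe
D07	NPR3	up_in_severe
D07	PBK	down_in_severe
D07	PIGR	down_in_severe
D07	RGL2	up_in_severe
D07	SLIT2	up_in_severe
D07	TOE1	down_in_severe
D07	TSPAN2	up_in_severe
D07	TTLL12	down_in_severe
D08	AGPAT5	down_in_severe
D08	ATP5B	down_in_severe
D08	CEP55	down_in_severe
D08	CONFLICTG	down_in_severe
D08	CXCL3	down_in_severe
D08	HNRNPAB	down_in_severe
D08	IDO1	down_in_severe
D08	NPR3	up_in_severe
D08	PBK	down_in_severe
D08	PIGR	down_in_severe
D08	RGL2	up_in_severe
D08	SLIT2	up_in_severe
D08	TOE1	down_in_severe
D08	TSPAN2	up_in_severe
D08	TTLL12	down_in_severe
D09	AGPAT5	down_in_severe
D09	ATP5B	down_in_severe
D09	CEP55	down_in_severe
D09	CONFLICTG	down_in_severe
D09	CXCL3	down_in_severe
D09	HNRNPAB	down_in_severe
D09	IDO1	down_in_severe
D09	NPR3	up_in_severe
D09	PBK	down_in_severe
D09	PIGR	down_in_severe
D09	RGL2	up_in_severe
D09	SLIT2	up_in_severe
D09	TOE1	down_in_severe
D09	TSPAN2	up_in_severe
D09	TTLL12	down_in_severe
D10	AGPAT5	down_in_severe
D10	ATP5B	down_in_severe
D10	AURKAIP1	down_in_severe
D10	CEP55	down_in_severe
D10	CONFLICTG	down_in_severe
D10	CXCL3	down_in_severe
D10	FUT4	down_in_severe
D10	HNRNPAB	down_in_severe
D10	IDO1	down_in_severe
D10	KIF11	down_in_severe
D10	PBK	down_in_severe
D10	PIGR	down_in_severe
D10	RANBP1	down_in_severe
D10	RGL2	up_in_severe
D10	SLIT2	up_in_severe
D10	TOE1	down_in_severe
D10	TSPAN2	up_in_severe
D10	TTLL12	down_in_severe
D11	ATP5B	down_in_severe
D11	AURKAIP1	down_in_severe
D11	CONFLICTG	down_in_severe
D11	CXCL3	down_in_severe
D11	FUT4	down_in_severe
D11	IDO1	down_in_severe
D11	KIF11	down_in_severe
D11	PIGR	down_in_severe
D11	RANBP1	down_in_severe
D11	RGL2	up_in_severe
D11	TSPAN2	up_in_severe
D11	TTLL12	down_in_severe
D12	ATP5B	down_in_severe
D12	AURKAIP1	down_in_severe
D12	CONFLICTG	down_in_severe
D12	CXCL3	down_in_severe
D12	FUT4	down_in_severe
D12	IDO1	down_in_severe
D12	KIF11	down_in_severe
D12	PIGR	down_in_severe
D12	RANBP1	down_in_severe
D12	TSPAN2	up_in_severe
D12	TTLL12	down_in_severe
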