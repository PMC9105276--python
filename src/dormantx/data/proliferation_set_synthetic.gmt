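proliferation	synthetic placeholder proliferation signature, sized like the published 131-gene set (non-canonical, for testing)	MKI67	PCNA	TOP2A	MCM2	MCM3	MCM4	MCM5	MCM6	MCM7	CCNB1	CCNB2	CCNA2	CCNE1	CCNE2	CDK1	CDK2	CDC20	CDC45	CDC6	CDC25A	CDC25B	CDC25C	BUB1	BUB1B	BUB3	PLK1	PLK4	AURKA	AURKB	BIRC5	TYMS	RRM1	RRM2	E2F1	E2F2	E2F8	FOXM1	CENPA	CENPE	CENPF	KIF11	KIF2C	KIF23	KIF20A	KIF4A	TK1	UBE2C	ZWINT	MYBL2	CHEK1	CHEK2	TTK	NDC80	NUF2	SPC24	SPC25	MAD2L1	ESPL1	PTTG1	ANLN	ASPM	TPX2	PRC1	RACGAP1	ECT2	GINS1	GINS2	GINS3	GINS4	ORC1	ORC6	POLA1	POLE2	POLD1	FEN1	RFC3	RFC4	RFC5	RPA3	DTL	GMNN	CDT1	EXO1	CLSPN	BLM	WDR76	HELLS	UHRF1	DNMT1	TIMELESS	TIPIN	MCM10	DSCC1	CHAF1A	CHAF1B	SLBP	STMN1	NUSAP1	DLGAP5	HMMR	MELK	TRIP13	OIP5	SGO1	SGO2	CDCA2	CDCA3	CDCA5	CDCA8	SKA1	SKA3	KNL1	SPAG5	ERCC6L	NCAPD2	NCAPG	NCAPH	SMC2	SMC4	TACC3	CKAP2	CKAP5	CKS1B	CKS2	GTSE1	HJURP	MIS18A	NEK2	PBK	PKMYT1	WEE1
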