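Chemokine	immunomodulatory gene group	CCL20	CXCL11	CXCL9	CXCL10	CCL2	CCL5	CXCL8	CXCL12
Chemokine receptor	immunomodulatory gene group	CCR6	CXCR3	CXCR4	CCR7	ACKR3
Interferon	immunomodulatory gene group	IFNG	IFNA1	IFNB1	IFNL1
IFN Receptor	immunomodulatory gene group	IFNGR1	IFNGR2	IFNAR1	IFNAR2	IFNLR1
Interleukin	immunomodulatory gene group	IL32	IL33	IL6	IL1B	IL10	IL15	IL18	IL7
Interleukin receptors	immunomodulatory gene group	IL6R	IL5RA	IL2RG	IL13RA1	IL17RA	IL17RD	IL20RA	IL4R	IL6ST	IL17RC	IL1R1	IL10RA	IL15RA
TNFSF	immunomodulatory gene group	TNFSF10	TNF	TNFSF11	TNFSF13B	FASLG
TNFRSF	immunomodulatory gene group	TNFRSF25	TNFRSF12A	TNFRSF11B	TNFRSF19	LTBR	TNFRSF14	TNFRSF21	TNFRSF1A	FAS	CD40
B7 family	immunomodulatory gene group	VTCN1	ICOSLG	NCR3LG1	CD276	CD274	PDCD1LG2	CD80	CD86
BMP	immunomodulatory gene group	BMP2	BMP4	BMP6	BMP7	GDF15
BMP Receptors	immunomodulatory gene group	BMPR1A	BMPR1B	BMPR2	ACVR1B	ACVR1	ACVR2A
MHC-related	immunomodulatory gene group	HLA-A	HLA-B	HLA-C	HLA-E	HLA-F	HLA-G	CD74	B2M	HLA-DPA1	HLA-DPB1	HLA-DRA	HLA-DRB1	HLA-DMA	HLA-DMB	HLA-DQA1	NLRC5	CIITA	TAP1	TAP2
Complement	immunomodulatory gene group	CLU	C3	C1QA	C5	CFB
Complement regulator	immunomodulatory gene group	CD46	CD59	CD55	CFH	SERPING1
Mucin	immunomodulatory gene group	MUC12	MUC1	MUC4	MUC16
Colony Stimulating Factor	immunomodulatory gene group	CSF1	CSF2	CSF3
TLR	immunomodulatory gene group	TLR5	TLR4	TLR2	TLR3	TLR9
PGE2 metabolism	immunomodulatory gene group	PTGS2	PTGS1	PTGES	HPGD	PTGES2	PTGES3
TGFBR	immunomodulatory gene group	TGFBR3	TGFBR1	TGFBR2
TGFB	immunomodulatory gene group	TGFB1	TGFB2	TGFB3
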