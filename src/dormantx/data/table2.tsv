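family	gene	full_name	direction
BMP Receptors	BMPR1B	Bone Morphogenetic Protein Receptor Type 1B	Down
Chemokine	CCL20	Chemokine (C-C motif) ligand 20	Up
Chemokine	CXCL11	C-X-C motif chemokine 11	Up
Complement	CLU	Clusterin	Up
Colony Stimulating Factor	CSF1	Colony Stimulating Factor 1	Up
MHC-related	HLA-A	MHC I, A	Up
MHC-related	HLA-B	MHC I, B	Up
MHC-related	HLA-E	non-classical MHC I, alpha chain E	Up
MHC-related	HLA-F	non-classical MHC I, alpha chain F	Up
MHC-related	CD74	Invariant chain	Up
MHC-related	B2M	beta2 microglobulin	Up
MHC-related	HLA-DPA1	MHC II, DP alpha chain	Up
MHC-related	HLA-DPB1	MHC II, DP Beta 1	Up
MHC-related	HLA-DRA	MHC II, DR alpha chain	Up
MHC-related	HLA-DMA	MHC II, DM alpha chain	Up
MHC-related	HLA-DMB	MHC II, DM beta chain	Down
Interleukin	IL32	Interleukin 32	Up
Interleukin	IL33	Interleukin 33	Up
Interleukin receptors	IL6R	Interleukin 6 Receptor	Up
Interleukin receptors	IL5RA	Interleukin 5 Receptor Subunit Alpha	Up
Interleukin receptors	IL2RG	Interleukin 2 Receptor Subunit Gamma	Up
B7 family	VTCN1	V-Set Domain Containing T Cell Activation Inhibitor 1	Up
B7 family	ICOSLG	Inducible T Cell Costimulator Ligand	Up
B7 family	NCR3LG1	Natural Killer Cell Cytotoxicity Receptor 3 Ligand 1	Up
Mucin	MUC12	Mucin 12, Cell Surface Associated	Up
TGFBR	TGFBR3	Transforming Growth Factor Beta Receptor 3	Up
TLR	TLR5	Toll-like receptor 5	Up
TNFRSF	TNFRSF25	TNF Receptor Superfamily Member 25	Up
TNFRSF	TNFRSF12A	TNF Receptor Superfamily Member 12A	Up
TNFRSF	TNFRSF11B	TNF receptor superfamily member 11B	Up
PGE2 metabolism	PTGS2	Prostaglandin-Endoperoxide Synthase 2	Down
PGE2 metabolism	PTGS1	Prostaglandin-Endoperoxide Synthase 1	Up
PGE2 metabolism	PTGES	Prostaglandin E Synthase	Up
PGE2 metabolism	HPGD	15-Hydroxyprostaglandin Dehydrogenase	Down
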