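family	family_printed	gene	full_name
BMP Receptors	BMP Receptors	BMPR1A	Bone morphogenetic protein receptor type 1A
BMP Receptors	BMP Receptors	BMPR2	Bone morphogenetic protein receptor type 2
BMP Receptors	BMP Receptors	ACVR1B	Activin A receptor type 1B
Complement regulator	Complement regulator	CD46	CD46 molecule
Complement regulator	Complement regulator	CD59	CD59 molecule
MHC-related	MHC-related	HLA-C	Major histocompatibility complex, class I, C
Interleukin receptors	IL Receptors	IL13RA1	Interleukin 13 receptor subunit alpha 1
Interleukin receptors	IL Receptors	IL17RA	Interleukin 17 receptor A
Interleukin receptors	IL Receptors	IL17RD	Interleukin 17 receptor D
Interleukin receptors	IL Receptors	IL20RA	Interleukin 20 receptor subunit alpha
Interleukin receptors	IL Receptors	IL4R	Interleukin 4 receptor
Interleukin receptors	IL Receptors	IL6ST	Interleukin 6 signal transducer
Interleukin receptors	IL Receptors	IL17RC	Interleukin 17 receptor C
Interleukin receptors	IL Receptors	IL1R1	Interleukin 1 receptor type 1
B7 family	B7 family	CD276	B7-H3
IFN Receptor	IFN Receptor	IFNGR2	Interferon gamma receptor 2
IFN Receptor	IFN Receptor	IFNAR1	Interferon alpha and beta receptor subunit 1
IFN Receptor	IFN Receptor	IFNGR1	Interferon gamma receptor 1
TGFBR	TGFBR	TGFBR1	Transforming growth factor beta receptor 1
TNFSF	TNFSF	TNFSF10	TNF superfamily member 10
TNFRSF	TNFRSF	TNFRSF19	TNF receptor superfamily member 19
TNFRSF	TNFRSF	LTBR	Lymphotoxin beta receptor
TNFRSF	TNFRSF	TNFRSF14	TNF receptor superfamily member 14
TNFRSF	TNFRSF	TNFRSF21	TNF receptor superfamily member 21
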