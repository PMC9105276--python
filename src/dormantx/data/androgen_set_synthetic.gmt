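androgen_responsive	synthetic placeholder androgen-responsive signature (non-canonical, for testing)	KLK3	KLK2	TMPRSS2	NKX3-1	FKBP5	NDRG1	PMEPA1	STEAP4	ABCC4	CAMKK2	ZBTB10	EAF2	HOMER2	MAF	SLC45A3
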