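EXHAUSTION_UP_SYNTHETIC	Synthetic stand-in for a 107-gene T-cell exhaustion up-signature (canonical exhaustion-associated symbols); substitute any GMT for real analyses	LAG3	HAVCR2	CTLA4	TIGIT	TBX21	IFNG	CCL1	CCL3	CCL4	CCL5	ENTPD1	PDCD1	TOX	EOMES	CD244	CD160	BTLA	CD38	CD101	CXCL13	PRDM1	NR4A2	RGS16	SH2D2A	IKZF2	ISG20	VSIR	CD200	CD200R1	IL10	IL21	CXCR5	CX3CR1	SIRPG	DUSP4	LAYN	ITGAE	PHLDA1	SNX9	TNFSF9	TNFRSF9	TNFRSF18	TNFRSF4	TNFRSF1B	CD7	CD27	CASP3	CASP4	LITAF	PTPN13	PTGER4	RGS1	SNAP47	TRIB1	PENK	LYST	RAB27A	CD82	SERPINA3	FASLG	BATF	TOX2	NR4A1	NR4A3	EGR2	EGR3	IRF8	MAF	VAV3	RGS2	CTSW	GOLIM4	PTMS	CCND2	PAG1	ADGRG1	KIR2DL4	KLRC1	KLRC2	JAML	AKAP5	SYNGR2	PKM	IFI35	ISG15	STAT1	STAT3	JAK3	SOCS1	SOCS3	IL2RB	IL2RG	CCR8	CXCL10	CXCL9	IDO1	HLA-DRA	HLA-DRB1	CD74	GBP2	GBP5	SLAMF6	SLAMF7	CD48	CD84	SH2D1A	UBASH3B
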