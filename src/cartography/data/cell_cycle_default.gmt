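S_PHASE	default S-phase gene module	MCM2	MCM3	MCM4	MCM5	MCM6	PCNA	POLA1	PRIM1	RRM1	RRM2	TYMS	FEN1	GINS2	CDC45	UHRF1	HELLS	MSH2	RFC4	SLBP	WDR76
G2M_PHASE	default G2/M gene module	MKI67	TOP2A	CCNB1	CCNB2	CDK1	BUB1	BUB1B	PLK1	AURKA	AURKB	CDC20	UBE2C	BIRC5	TPX2	KIF11	KIF23	CENPA	CENPE	NUSAP1	SMC4
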