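disulfidptosis_positive	positive regulators of disulfidptosis (CRISPR screen)	SLC7A11	SLC3A2	RPN1	NCKAP1	CYFIP1	ABI2	WASF2	BRK1	RAC1
disulfidptosis_negative	negative regulators of disulfidptosis (CRISPR screen)	GYS1	NDUFS1	OXSM	LRPPRC	NDUFA11	NUBPL	G6PD	PGD	TALDO1	TKT	SLC2A1	SLC2A3
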