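drug	target_gene	default_weight
sorafenib	BRAF	0
sorafenib	RAF1	0
sorafenib	FLT3	0
sorafenib	FLT4	0
sorafenib	PDGFRB	0
sorafenib	KIT	0
sorafenib	FGFR1	0
sorafenib	RET	0
sorafenib	FLT1	0
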