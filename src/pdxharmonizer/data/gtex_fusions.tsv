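# Starter list of chimeric transcripts observed in normal tissue (editable).
gene5	gene3
KANSL1	ARL17A
KANSL1	ARL17B
TFG	GPR128
CTBS	GNG5
SLC45A3	ELK4
TTTY15	USP9Y
AZGP1	GJC3
HARS2	ZMAT2
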