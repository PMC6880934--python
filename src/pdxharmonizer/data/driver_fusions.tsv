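# Starter list of literature/cytogenetics-validated driver fusions (editable).
gene5	gene3
EWSR1	FLI1
BCR	ABL1
PAX3	FOXO1
PAX7	FOXO1
ETV6	RUNX1
KMT2A	AFF1
KMT2A	MLLT3
KMT2A	MLLT1
ASPSCR1	TFE3
CIC	DUX4
P2RY8	CRLF2
EWSR1	ERG
TCF3	PBX1
NUP98	KDM5A
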