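# Starter kinase list (editable).
gene
ABL1
ALK
BRAF
JAK1
JAK2
JAK3
NTRK1
NTRK2
NTRK3
EGFR
KIT
PDGFRA
PDGFRB
FGFR1
FGFR2
RET
CDK4
CDK6
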