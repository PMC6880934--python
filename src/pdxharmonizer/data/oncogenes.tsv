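# Starter oncogene list (editable).
gene
MYC
MYCN
ALK
ABL1
KRAS
NRAS
HRAS
BRAF
JAK2
FLI1
ERG
CRLF2
NOTCH1
CTNNB1
EGFR
KIT
PDGFRA
MDM2
CDK4
DUX4
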