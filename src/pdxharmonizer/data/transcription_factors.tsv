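# Starter transcription-factor list (editable).
gene
FLI1
ERG
FOXO1
PAX3
PAX5
PAX7
RUNX1
TFE3
ETV6
MYC
MYCN
DUX4
WT1
TCF3
PBX1
NOTCH1
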