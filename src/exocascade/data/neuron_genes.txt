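# Example gene list for the keyword "neuron" (neuronal-function genes).
# Illustrative only — supply a curated list for real analyses.
FXN
MFN2
MYOC
NPC1
PSEN1
RET
SPG7
SCN3A
SCN1A
SCN2A
SCN8A
KCNQ2
KCNQ3
CACNA1A
GRIN1
GRIN2A
GRIN2B
SYN1
SYT1
STXBP1
SNAP25
MAPT
APP
NEFL
GABRA1
SLC6A3
TH
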