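# Example gene list for the keyword "PD" (parkinsonism-associated genes).
# Illustrative only — supply a curated list for real analyses.
FXN
MFN2
MYOC
NPC1
PSEN1
RET
SPG7
SNCA
LRRK2
PRKN
PINK1
PARK7
VPS35
GBA
ATP13A2
DNAJC6
SYNJ1
CHCHD2
VPS13C
UCHL1
GIGYF2
HTRA2
PLA2G6
FBXO7
EIF4G1
DNAJC13
RAB39B
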