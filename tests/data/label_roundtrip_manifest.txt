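# QUDT codes whose vocabulary label maps back to the same code
# through the default pseudounit + rewrite pipeline.
# Excluded: MicroG-PER-CentiM2 (QUDT's own pattern-inconsistent
# legacy code; the rules produce the consistent MicroGM-PER-CentiM2).
CentiM
CentiM-PER-SEC
CentiM2
CentiM3
DAY
DEG
DEG_C
DEG_F
GM
GM-PER-CentiM2
GM-PER-L
GM-PER-M2
GM-PER-M2-DAY
HA
HR
HZ
HectoPA
J
K
KiloGM
KiloGM-PER-HA
KiloGM-PER-M2
KiloM
KiloM-PER-HR
KiloM2
KiloPA
L
M
M-PER-SEC
M2
M3
MIN
MOL
MOL-PER-L
MicroGM
MicroGM-PER-L
MicroM
MicroMOL
MicroMOL-PER-L
MicroMOL-PER-M2-SEC
MilliGM
MilliGM-PER-L
MilliGM-PER-M2
MilliL
MilliM
MilliMOL
MilliMOL-PER-L
NUM
NUM-PER-M2
NanoM
PA
PER-M2
PER-SEC
PERCENT
PERMILLE
SEC
UNITLESS
W
W-PER-M2
YR
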