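TP53
FAT1
CDKN2A
PIK3CA
NOTCH1
KMT2D
NSD1
CASP8
AJUBA
NFE2L2
TGFBR2
HRAS
FBXW7
RB1
PIK3R1
TRAF3
CUL3
PTEN
EP300
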