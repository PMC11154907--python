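TP53
NOTCH1
PIK3CA
KMT2D
CDKN2A
CASP8
NSD1
FAT1
FBXW7
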