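gene	chrom	start	end
TP53	chr17	7668000	7688000
FAT1	chr4	186587000	186727000
CDKN2A	chr9	21967000	21995000
PIK3CA	chr3	179148000	179240000
NOTCH1	chr9	136494000	136546000
KMT2D	chr12	49018000	49060000
NSD1	chr5	177133000	177300000
CASP8	chr2	201233000	201287000
AJUBA	chr14	23000000	23015000
NFE2L2	chr2	177230000	177265000
TGFBR2	chr3	30606000	30694000
HRAS	chr11	532000	537000
FBXW7	chr4	152320000	152536000
RB1	chr13	48303000	48481000
PIK3R1	chr5	68215000	68301000
TRAF3	chr14	102770000	102900000
CUL3	chr2	224470000	224585000
PTEN	chr10	87863000	87971000
EP300	chr22	41092000	41180000
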