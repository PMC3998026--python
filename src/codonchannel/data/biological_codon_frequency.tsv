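codon	frequency
TTT	0.0191
TTC	0.0196
TTA	0.0085
TTG	0.0141
TCT	0.0171
TCC	0.0160
TCA	0.0133
TCG	0.0043
TAT	0.0132
TAC	0.0160
TAA	0.0003
TAG	0.0001
TGT	0.0110
TGC	0.0119
TGA	0.0003
TGG	0.0125
CTT	0.0150
CTC	0.0173
CTA	0.0080
CTG	0.0373
CCT	0.0176
CCC	0.0150
CCA	0.0178
CCG	0.0059
CAT	0.0116
CAC	0.0144
CAA	0.0137
CAG	0.0337
CGT	0.0054
CGC	0.0087
CGA	0.0062
CGG	0.0085
ATT	0.0175
ATC	0.0200
ATA	0.0094
ATG	0.0219
ACT	0.0144
ACC	0.0160
ACA	0.0169
ACG	0.0059
AAT	0.0182
AAC	0.0206
AAA	0.0282
AAG	0.0319
AGT	0.0136
AGC	0.0191
AGA	0.0135
AGG	0.0118
GTT	0.0136
GTC	0.0138
GTA	0.0084
GTG	0.0265
GCT	0.0200
GCC	0.0213
GCA	0.0179
GCG	0.0060
GAT	0.0252
GAC	0.0246
GAA	0.0311
GAG	0.0389
GGT	0.0115
GGC	0.0176
GGA	0.0184
GGG	0.0133
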