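codon	frequency
TTT	0.0257
TTC	0.0264
TTA	0.0097
TTG	0.0119
TCT	0.0113
TCC	0.0150
TCA	0.0100
TCG	0.0066
TAT	0.0207
TAC	0.0260
TGT	0.0215
TGC	0.0247
TGG	0.0439
CTT	0.0118
CTC	0.0150
CTA	0.0054
CTG	0.0277
CCT	0.0159
CCC	0.0162
CCA	0.0161
CCG	0.0085
CAT	0.0141
CAC	0.0183
CAA	0.0144
CAG	0.0337
CGT	0.0073
CGC	0.0129
CGA	0.0077
CGG	0.0065
ATT	0.0162
ATC	0.0205
ATA	0.0088
ATG	0.0330
ACT	0.0071
ACC	0.0128
ACA	0.0093
ACG	0.0079
AAT	0.0160
AAC	0.0212
AAA	0.0251
AAG	0.0261
AGT	0.0130
AGC	0.0163
AGA	0.0157
AGG	0.0122
GTT	0.0096
GTC	0.0114
GTA	0.0060
GTG	0.0260
GCT	0.0132
GCC	0.0172
GCA	0.0110
GCG	0.0048
GAT	0.0234
GAC	0.0228
GAA	0.0235
GAG	0.0263
GGT	0.0114
GGC	0.0162
GGA	0.0183
GGG	0.0126
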