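allele,assay,signal
S1,intron1_SR1,390
S2,intron1_SR1,285
S3,intron1_SR1,300
S4,intron1_SR1,260
S5,intron1_SR1,310
S6,intron1_SR1,none
S7,intron1_SR1,390
S8,intron1_SR1,410
S9,intron1_SR1,320
S11,intron1_SR1,330
S15,intron1_SR1,340
S17,intron1_SR1,427
S19,intron1_SR1,none
S20,intron1_SR1,none
S24,intron1_SR1,none
S31,intron1_SR1,350
SC,intron1_SR1,410
SV,intron1_SR1,370
SX,intron1_SR1,none
SZ,intron1_SR1,360
S1,intron1_PruT2,none
S2,intron1_PruT2,none
S3,intron1_PruT2,none
S4,intron1_PruT2,none
S5,intron1_PruT2,none
S6,intron1_PruT2,450
S7,intron1_PruT2,none
S8,intron1_PruT2,none
S9,intron1_PruT2,none
S11,intron1_PruT2,none
S15,intron1_PruT2,none
S17,intron1_PruT2,none
S19,intron1_PruT2,none
S20,intron1_PruT2,none
S24,intron1_PruT2,470
S31,intron1_PruT2,none
SC,intron1_PruT2,none
SV,intron1_PruT2,none
SX,intron1_PruT2,none
SZ,intron1_PruT2,none
S1,intron2_C2C6,350
S2,intron2_C2C6,410
S3,intron2_C2C6,none
S4,intron2_C2C6,480
S5,intron2_C2C6,770
S6,intron2_C2C6,770
S7,intron2_C2C6,560
S8,intron2_C2C6,2800
S9,intron2_C2C6,660
S11,intron2_C2C6,900
S15,intron2_C2C6,1050
S17,intron2_C2C6,1440
S19,intron2_C2C6,1230
S20,intron2_C2C6,1230
S24,intron2_C2C6,300
S31,intron2_C2C6,1690
SC,intron2_C2C6,2800
SV,intron2_C2C6,1230
SX,intron2_C2C6,2320
SZ,intron2_C2C6,1980
S1,sfb_5utr,210
S2,sfb_5utr,195
S3,sfb_5utr,192
S4,sfb_5utr,none
S5,sfb_5utr,none
S6,sfb_5utr,197
S7,sfb_5utr,202
S8,sfb_5utr,199
S9,sfb_5utr,none
S11,sfb_5utr,195
S15,sfb_5utr,205
S17,sfb_5utr,189
S19,sfb_5utr,none
S20,sfb_5utr,none
S24,sfb_5utr,none
S31,sfb_5utr,207
SC,sfb_5utr,199
SV,sfb_5utr,none
SX,sfb_5utr,none
SZ,sfb_5utr,207
S1,sfb_insertion,0
S2,sfb_insertion,0
S3,sfb_insertion,0
S4,sfb_insertion,0
S5,sfb_insertion,0
S6,sfb_insertion,0
S7,sfb_insertion,0
S8,sfb_insertion,0
S9,sfb_insertion,0
S11,sfb_insertion,0
S15,sfb_insertion,0
S17,sfb_insertion,0
S19,sfb_insertion,0
S20,sfb_insertion,0
S24,sfb_insertion,0
S31,sfb_insertion,0
SC,sfb_insertion,1
SV,sfb_insertion,0
SX,sfb_insertion,0
SZ,sfb_insertion,0
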