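name,repeat_motif_length,genomic_anchor
PGS3.71,2,chr3-distal
PGS3.22,2,chr3-distal
PGS3.62,2,chr3-distal
PGS3.23,2,chr3-distal
PGS3.96,2,chr3-distal
AGS.20,2,chr3-distal
AGS.30,2,chr3-distal
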