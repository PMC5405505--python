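parent,allele_a,allele_b,n_hom_a,n_het,n_hom_b,n_total,n_analyzed,m_marker,note
Bebecou,S6,SC,0,33,45,96,78,,
Dulcinea,SC,S2,36,37,0,104,73,,printed chi2 values (0.34 and 37.9) do not match Pearson recomputation from these counts
Corbato,S2,S5,10,17,9,44,36,PGS3.23,no homozygote for the SSR allele in repulsion with m0 was detected
Portici,S2,S20,16,24,4,59,44,AGS.20,no homozygote for the SSR allele in repulsion with m0 was detected; S2/S2 count unexpectedly high
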