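accession,bagged_flowers,fruits_set,phenotype,progeny_n
Alba,355,37,SC,1
Aurora,350,0,SI,0
Bebecou,760,108,SC,96
Bulida,200,1,SC?,0
Canino,412,99,SC,99
Castlebrite,300,36,SC,2
Corbato,320,52,SC,44
Cow-1,200,8,SC,7
Cow-2,315,0,SI,0
Cristali,200,24,SC,13
Dulcinea,850,111,SC,104
Ezzine,350,160,SC,21
Galta Roja,775,106,SC,106
Katy,731,80,SC,80
Mariem,450,11,SC?,11
Ninfa,400,221,SC,12
Perla,370,0,SI,0
Portici,850,63,SC,59
Tadeo,375,14,SC,5
Veecot,450,0,SI,0
Velazquez,270,0,SI,0
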