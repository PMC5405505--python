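id,name,geographic_group,phenotype,s_genotype,m_genotype,clonal_parent
1,Alba,WE,SC,S1/SC,M1-1/M3,
2,ASP,WE,male-sterile,S5/SC,M4-0/M5-1,
3,Aurora,NA,SI,S1/S17,M3/M11,
4,Bebecou,SE/NAf,SC,S6/SC,M4-0/M4-2,
5,Bergeron,WE,SC,S2/SC,M4-0/M8-0,
6,Budapest,EE,SC,S2/SC,M1-1/M12,
7,Bulida,SE/NAf,SC,S5/SC,M4-1/M5-1,
8,Canino,WE,SC,S2/SC,M1-0/m0-0,
9,Canino 9-7,WE,undetermined,S2/SC,M1-0/m0-0,Canino
10,Canino 14-4,WE,SC,S2/SC,M1-0/m0-0,Canino
11,Canino 14-6,WE,SC,S2/SC,M1-0/m0-0,Canino
12,Castlebrite,NA,SC,S2/S2,M3/m0-0,
13,Castleton,NA,SC,S1/S2,M3/m0-0,
14,Cegledi orias,EE,SI,S8/S9,M12/M13,
15,Colorao,SE/NAf,male-sterile,S5/SC,M4-0/M4-0,
16,Corbato,WE,SC,S2/S5,M5-0/m0-0,
17,Cow-1,WE,SC,S1/S31,M3/m0-0,
18,Cow-2,WE,SI,S20/S31,M1-0/m0-0,
19,Cristali,WE,SC,S20/SC,M5-0/m0-0,
20,Currot,WE,SC,SC/SC,m0-0/m0-0,
21,Dulcinea,WE,SC,S2/SC,M7-3/M14-1,
22,Effect,EE,SC,S8/SC,M8-0/M12,
23,Ezzine,SE/NAf,SC,S24/SC,M1-0/M7-1,
24,Fergani,EE,undetermined,SV/SX,?/?,
25,Galta Roja,WE,SC,SC/SC,M4-0/M5-2,
26,GVV,WE,undetermined,S2/SC,M4-0/M5-2,
27,Gandia,WE,undetermined,SC/SC,m0-0/m0-0,
28,Gavatxet,WE,undetermined,S20/SC,m0-0/m0-0,
29,Ginesta,WE,SC,SC/SC,m0-0/m0-0,
30,Goldrich,NA,SI,S1/S2,M1-0/M2-0,
31,Gonci Magyar,EE,SC,S8/SC,M8-0/M12,
32,Harcot,NA,SI,S1/S4,M1-0/M2-2,
33,Hargrand,NA,SI,S1/S2,M1-0/M2-0,
34,Harlayne,NA,SC,S3/S20,M2-0/M9,
35,Henderson,NA,SC,S3/S17,M2-0/M16,
36,Katy,NA,SC,S1/S2,M3/m0-0,
37,Kech-pshar,EE,undetermined,S15/SZ,?/?,
38,Konservnyi Pozdnii,EE,SC,S2/SC,M4-1/M8-1,
39,Lambertin-1,NA,SI,S1/S2,M1-0/M17,
40,Lito,SE/NAf,SC,S6/SC,M6/M10,
41,Manri,WE,undetermined,SC/SC,m0-0/m0-0,
42,Mari de Cenad,EE,SC,SC/S19,M8-0/M18,
43,Mariem,SE/NAf,SC,S7/S20,M1-0/M8-2,
44,Martinet,WE,undetermined,S2/S2,m0-0/m0-1,
45,Mitger,WE,SC,SC/SC,M5-0/M5-0,
46,Moniqui,SE/NAf,SI,S2/S6,M4-1/M14-0,
47,Ninfa,WE,SC,S7/SC,M7-0/M10,
48,Orange Red,NA,SI,S6/S17,M2-0/M2-1,
49,Ouardi,SE/NAf,SI,S2/S7,M1-0/M7-0,
50,Palabras,WE,SC,SC/SC,m0-0/m0-0,
51,Palau,WE,SC,SC/SC,m0-0/m0-0,
52,Patterson,NA,SC,S1/SC,M1-3/M3,
53,Perla,WE,SI,S2/S20,M1-2/M15-1,
54,Portici,WE,SC,S2/S20,M1-4/m0-0,
55,Rojo de Carlet,WE,SC,SC/SC,M4-0/M5-0,
56,Rozsakajszi,EE,SC,S2/SC,M1-0/M12,
57,Sayeb,SE/NAf,SC,S7/SC,M1-0/M7-2,
58,Shalah,EE,SC,S5/S11,M8-1/M19,
59,SEO,NA,SI,S6/S17,M2-0/M6,
60,Stella,NA,SI,S6/S20,M9/M9,
61,Szegedi Mammut,EE,SI,S8/S9,M12/M13,
62,Tadeo,WE,SC,S20/SC,M15-0/m0-0,
63,Tirynthos,SE/NAf,SC,SC/SC,M10/M10,
64,Trevatt,NA,SC,S2/SC,M1-0/m0-0,
65,Veecot,NA,SI,S2/S20,M2-0/M3,
66,Velazquez,SE/NAf,SI,S5/S20,M4-0/M4-1,
67,Xirivello,WE,undetermined,SC/SC,M4-0/M4-1,
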