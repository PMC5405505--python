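haplotype,PGS3.71,PGS3.22,PGS3.62,PGS3.23,PGS3.96,AGS.20,AGS.30
m0-0,100,140,180,220,260,280,300
m0-1,100,140,180,220,262,280,300
M1-0,102,142,182,222,262,282,300
M1-1,102,142,182,222,262,280,300
M1-2,102,142,182,222,260,280,300
M1-3,102,142,182,222,262,284,300
M1-4,102,142,182,222,264,284,300
M2-0,108,148,188,228,260,280,300
M2-1,108,148,188,228,262,280,300
M2-2,108,148,188,228,264,280,300
M3,118,158,198,238,260,280,300
M4-0,132,172,212,252,260,280,300
M4-1,132,172,212,252,262,280,300
M4-2,132,172,212,252,264,280,300
M5-0,150,190,230,270,260,280,300
M5-1,150,190,230,270,262,280,300
M5-2,150,190,230,270,264,280,300
M6,172,212,252,292,260,280,300
M7-0,198,238,278,318,260,280,300
M7-1,198,238,278,318,262,280,300
M7-2,198,238,278,318,264,280,300
M7-3,198,238,278,318,266,280,300
M8-0,228,268,308,348,260,280,300
M8-1,228,268,308,348,262,280,300
M8-2,228,268,308,348,264,280,300
M9,262,302,342,382,260,280,300
M10,300,340,380,420,260,280,300
M11,342,382,422,462,260,280,300
M12,388,428,468,508,260,280,300
M13,438,478,518,558,260,280,300
M14-0,492,532,572,612,260,280,300
M14-1,492,532,572,612,262,280,300
M15-0,550,590,630,670,260,280,300
M15-1,550,590,630,670,262,280,300
M16,612,652,692,732,260,280,300
M17,678,718,758,798,260,280,300
M18,748,788,828,868,260,280,300
M19,822,862,902,942,260,280,300
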