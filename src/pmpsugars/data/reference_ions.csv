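species,class,rt_min,precursor_mz,ppm_error,mh_h2o,c3c4_h2o,c2c3_h2o,mh_pmp,mh_pmp_h2o,mh_pmp_2h2o,mh_pmp_3h2o,c5c6_2h2o,c4c5_2h2o,c2c3,c1c2,pmp_h
mannose,hexose,33.830,511.2201,+2.74,493.2283,403.1312,373.1751,337.1331,319.1064,301.1157,283.1149,271.1069,241.1037,217.1045,187.0860,175.0904
glucosamine,hexosamine,36.548,510.2350,+0.59,492.2207,402.1679,372.1868,336.1679,319.1589,301.0892,283.1082,271.1083,241.0959,216.1313,187.0923,175.0904
lyxose,pentose,40.298,481.2061,-4.36,463.2209,,373.1593,307.1321,289.1476,271.1193,253.1302,,241.1071,217.1093,187.0893,175.0873
rhamnose,methylpentose,47.701,495.2243,+1.01,,,373.1729,321.1649,303.1136,285.1227,267.1122,,241.0933,217.0929,187.0924,175.0902
ribose,pentose,48.832,481.2073,-1.87,463.2216,,373.1750,307.1325,289.1153,271.1021,253.1001,,241.0979,217.1053,187.0901,175.0919
erythrose,tetrose,64.678,451.1977,+0.22,433.1797,,373.1749,277.1583,259.1082,241.0970,,,,217.0938,187.0943,175.0861
glucuronic acid,hexuronic_acid,94.865,525.1972,-1.52,507.1776,,373.1567,,,,297.0914,271.0983,241.0941,217.1039,187.0796,175.0838
galacturonic acid,hexuronic_acid,107.503,525.2005,+4.76,507.1841,,373.1733,,,,297.0766,271.0983,241.1252,217.1018,187.0809,175.0875
glucose,hexose,115.318,511.2187,+0,493.1923,403.1419,373.1652,337.1408,319.1341,301.1345,283.1135,271.1116,241.0986,217.0986,187.0884,175.0860
galactose,hexose,130.080,511.2187,+0,493.2219,403.1561,373.1693,337.1036,319.1108,301.1322,283.1110,271.1120,241.1001,217.0951,187.0804,175.0872
xylose,pentose,145.282,481.2072,-2.08,463.1764,,373.1680,,289.1448,271.1019,253.0949,,241.1188,217.0712,187.0896,175.1019
fucose,methylpentose,166.837,495.2259,+4.24,477.2073,403.1800,373.1626,321.1555,,285.1205,267.1102,,241.1030,217.1096,187.0925,175.0906
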