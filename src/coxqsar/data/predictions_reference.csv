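# Published predicted pIC50 and residuals (delta = observed - predicted) for the
# four models, as printed (training + internal validation + external validation).
# The tri prediction for molecule 3 is printed to 3 decimals in the source (9.832);
# it is stored here as 9.8320, which the equation reproduces.
id,set,observed,mono,d_mono,bi,d_bi,tri,d_tri,tetra,d_tetra
1,training,7.9208,8.2562,-0.3354,8.0305,-0.1097,7.7961,0.1247,7.7670,0.1538
2,training,10.0457,9.2561,0.7896,9.5495,0.4962,9.5773,0.4684,9.5693,0.4764
3,training,9.7695,9.5894,0.1801,9.8339,-0.0644,9.8320,-0.0625,9.8414,-0.0719
4,training,9.6989,9.8116,-0.1127,9.6906,0.0083,9.6680,0.0309,9.7855,-0.0866
5,training,9.5528,9.2561,0.2967,9.5495,0.0033,9.5773,-0.0245,9.5693,-0.0165
6,training,9.4436,8.9228,0.5208,9.2651,0.1785,9.3226,0.1210,9.2972,0.1464
7,training,9.4317,8.9228,0.5089,9.2651,0.1666,9.3226,0.1091,9.2972,0.1345
8,training,9.2218,8.9228,0.2990,9.2651,-0.0433,9.3226,-0.1008,9.2972,-0.0754
9,training,9.0969,8.9228,0.1741,9.2651,-0.1682,9.3226,-0.2257,9.2972,-0.2003
10,training,9.0000,8.9228,0.0772,8.9322,0.0678,8.9888,0.0112,8.9925,0.0075
11,training,8.7447,8.3673,0.3774,7.7924,0.9523,8.5957,0.1490,8.6154,0.1293
12,training,8.4317,9.1450,-0.7133,8.4560,-0.0243,8.4910,-0.0593,8.4297,0.0020
13,training,8.3979,8.7006,-0.3027,8.7426,-0.3447,8.8190,-0.4211,8.8111,-0.4132
14,training,8.3767,8.9228,-0.5461,8.5993,-0.2226,8.3055,0.0712,8.2438,0.1329
15,training,8.3000,7.4785,0.8215,8.0327,0.2673,8.2189,0.0811,8.2529,0.0471
16,training,8.2518,8.8117,-0.5599,8.5045,-0.2527,8.5701,-0.3183,8.5297,-0.2779
17,training,8.2218,8.7006,-0.4788,8.4097,-0.1879,8.1357,0.0861,8.1972,0.0246
18,training,8.0969,8.2562,-0.1593,8.0305,0.0664,7.7961,0.3008,7.8344,0.2625
19,training,7.7212,8.2562,-0.5350,8.0305,-0.3093,7.7961,-0.0749,7.8344,-0.1132
20,training,7.6777,7.9229,-0.2452,8.0790,-0.4013,7.8752,-0.1975,7.8670,-0.1893
21,internal_validation,9.3010,9.0339,0.2671,9.0270,0.2740,8.7242,0.5768,8.7066,0.5944
22,internal_validation,8.8508,8.9228,-0.0720,9.2651,-0.4143,9.3226,-0.4718,9.2972,-0.4464
23,internal_validation,8.8239,9.3672,-0.5433,9.6443,-0.8204,9.3127,-0.4888,9.3508,-0.5269
24,internal_validation,8.6990,8.8117,-0.1127,8.8374,-0.1384,9.2534,-0.5544,9.2110,-0.5120
25,internal_validation,8.4815,9.0339,-0.5524,9.3599,-0.8784,9.0580,-0.5765,9.0787,-0.5972
26,external_validation,9.7447,9.3672,0.3775,9.3114,0.4333,9.6779,0.0668,9.6645,0.0802
27,external_validation,9.2676,8.8117,0.4559,8.8374,0.4302,9.2534,0.0142,9.2110,0.0566
28,external_validation,8.8508,8.9228,-0.0720,9.2651,-0.4143,9.3226,-0.4718,9.2972,-0.4464
29,external_validation,8.6198,9.7005,-1.0807,8.2642,0.3556,8.2479,0.3719,8.1390,0.4808
30,external_validation,8.2757,8.3673,-0.0916,8.1253,0.1504,8.2305,0.0452,8.1669,0.1088
31,external_validation,8.1549,7.8118,0.3431,8.3171,-0.1622,8.4736,-0.3187,8.5250,-0.3701
Celecoxib,external_validation,9.2839,8.7006,0.5833,8.4097,0.8742,8.4852,0.7987,8.4390,0.8449
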