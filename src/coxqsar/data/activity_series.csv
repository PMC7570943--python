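# Full activity series in ascending IC50 order: pivot + training (1-20),
# internal validation (21-25), external validation (26-31, celecoxib).
# Values are stored exactly as published; two rows carry known inconsistencies
# and are flagged in the note column rather than silently corrected.
id,name,role,ic50_nM,pic50,note
1,Rofecoxib(BDBM22369),pivot,12.000,7.9208,
2,BDBM50272105,training,0.090,10.0457,
3,BDBM50272097,training,0.170,9.7695,
4,BDBM50365267,training,0.200,9.6989,
5,BDBM50272130,training,0.280,9.5528,
6,BDBM50272111,training,0.360,9.4436,
7,BDBM50272124,training,0.370,9.4317,
8,BDBM50272106,training,0.600,9.2218,
9,BDBM50272092,training,0.800,9.0969,
10,BDBM50049011,training,1.000,9.0000,
11,BDBM50189988,training,1.800,8.7447,
12,BDBM50057618,training,3.700,8.4317,
13,BDBM50151689,training,4.000,8.3979,
14,BDBM50103310,training,4.200,8.3767,
15,BDBM13066,training,5.000,8.3000,printed pIC50 inconsistent with IC50 (recomputed 8.3010)
16,BDBM50297680,training,5.600,8.2518,
17,BDBM50026234,training,6.000,8.2218,
18,BDBM50332773,training,8.000,8.0969,
19,BDBM50332765,training,19.000,7.7212,
20,BDBM50336012,training,21.000,7.6777,
21,BDBM50029613,internal_validation,0.500,9.3010,
22,BDBM50272113,internal_validation,1.410,8.8508,
23,BDBM50049030,internal_validation,1.500,8.8239,
24,BDBM50272109,internal_validation,2.000,8.6990,
25,BDBM50049013,internal_validation,3.300,8.4815,
26,BDBM50272128,external_validation,0.180,9.7447,
27,BDBM50272090,external_validation,0.540,9.2676,
28,BDBM50272113,external_validation,1.410,8.8508,
29,BDBM50373566,external_validation,2.400,8.6198,
30,BDBM50057606,external_validation,5.300,8.2757,
31,BDBM50207446,external_validation,7.000,8.1549,
Celecoxib,Celecoxib(BDBM11639),external_validation,0.520,8.4390,printed pIC50 conflicts with validation-table observed 9.2839
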