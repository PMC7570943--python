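# Reference COX-2 inhibitor training set: 20 molecules from BindingDB with
# PharmaGist pharmacophore descriptor counts (ATM atoms, ARO aromatic features,
# DONN H-bond donors, ACC H-bond acceptors), IC50 in nM and pIC50 = -log10(IC50 [M]).
# Molecule 1 (rofecoxib) is the pivot of the pharmacophore alignment and is part
# of the 20-compound regression set.
id,name,role,ATM,ARO,DONN,ACC,ic50_nM,pic50,note
1,Rofecoxib(BDBM22369),pivot,36,2,0,4,12.00,7.9208,
2,BDBM50272105,training,45,4,1,2,0.09,10.0457,
3,BDBM50272097,training,48,4,1,2,0.17,9.7695,
4,BDBM50365267,training,50,2,1,3,0.20,9.6989,
5,BDBM50272130,training,45,4,1,2,0.28,9.5528,
6,BDBM50272111,training,42,4,1,2,0.36,9.4436,
7,BDBM50272124,training,42,4,1,2,0.37,9.4317,
8,BDBM50272106,training,42,4,1,2,0.60,9.2218,
9,BDBM50272092,training,42,4,1,2,0.80,9.0969,
10,BDBM50049011,training,42,3,1,3,1.00,9.0000,
11,BDBM50189988,training,37,2,3,5,1.80,8.7447,
12,BDBM50057618,training,44,3,1,5,3.70,8.4317,
13,BDBM50151689,training,40,3,1,3,4.00,8.3979,
14,BDBM50103310,training,42,3,0,4,4.20,8.3767,
15,BDBM13066,training,29,2,1,2,5.00,8.3000,printed pIC50 inconsistent with IC50 (recomputed 8.3010)
16,BDBM50297680,training,41,3,1,4,5.60,8.2518,
17,BDBM50026234,training,40,1,0,4,6.00,8.2218,
18,BDBM50332773,training,36,1,0,4,8.00,8.0969,
19,BDBM50332765,training,36,1,0,4,19.00,7.7212,
20,BDBM50336012,training,33,2,0,3,21.00,7.6777,
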