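# Internal validation set (molecules 21-25). Descriptor counts are not printed
# in the source tables; they were reconstructed uniquely from the four published
# prediction equations (the mono equation fixes ATM, bi fixes ACC, tri fixes DONN,
# tetra fixes ARO) and reproduce every published predicted pIC50 exactly at 4 dp.
id,name,role,ATM,ARO,DONN,ACC,ic50_nM,pic50,note
21,BDBM50029613,internal_validation,43,3,0,3,0.50,9.3010,descriptors reconstructed from published predictions
22,BDBM50272113,internal_validation,42,4,1,2,1.41,8.8508,descriptors reconstructed from published predictions
23,BDBM50049030,internal_validation,46,3,0,2,1.50,8.8239,descriptors reconstructed from published predictions
24,BDBM50272109,internal_validation,41,4,2,3,2.00,8.6990,descriptors reconstructed from published predictions
25,BDBM50049013,internal_validation,43,3,0,2,3.30,8.4815,descriptors reconstructed from published predictions
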