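# External validation set (molecules 26-31 plus the celecoxib control).
# Descriptor counts reconstructed from the four published prediction equations
# (see internal_validation.csv); celecoxib's descriptors match the published
# candidate table. Celecoxib's observed pIC50 is 9.2839 (consistent with its
# IC50 of 0.52 nM); the activity-series table elsewhere prints 8.4390 for the
# same molecule - that conflict is preserved and flagged, not resolved.
id,name,role,ATM,ARO,DONN,ACC,ic50_nM,pic50,note
26,BDBM50272128,external_validation,46,4,2,3,0.18,9.7447,descriptors reconstructed from published predictions
27,BDBM50272090,external_validation,41,4,2,3,0.54,9.2676,descriptors reconstructed from published predictions
28,BDBM50272113,external_validation,42,4,1,2,1.41,8.8508,descriptors reconstructed from published predictions
29,BDBM50373566,external_validation,49,3,1,7,2.40,8.6198,descriptors reconstructed from published predictions
30,BDBM50057606,external_validation,37,3,1,4,5.30,8.2757,descriptors reconstructed from published predictions
31,BDBM50207446,external_validation,32,2,1,2,7.00,8.1549,descriptors reconstructed from published predictions
Celecoxib,Celecoxib(BDBM11639),external_validation,40,3,1,4,0.52,9.2839,observed pIC50 follows validation table; activity series prints 8.4390
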