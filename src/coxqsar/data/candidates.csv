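# Screening candidates (Z-series) and reference controls with their pharmacophore
# descriptor counts, plus the published predicted pIC50 per model for cross-checking.
id,role,ATM,ARO,DONN,ACC,mono,bi,tri,tetra
Rofecoxib,control,36,2,0,4,8.2562,8.0305,7.7961,7.7670
Celecoxib,control,40,3,1,4,8.7006,8.4097,8.4852,8.4390
Z-814,candidate,38,2,0,4,8.4784,8.2201,7.9659,7.9484
Z-627,candidate,41,2,2,3,8.8117,8.8374,9.2534,9.3458
Z-964,candidate,43,2,2,3,9.0339,9.0270,9.4232,9.5272
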