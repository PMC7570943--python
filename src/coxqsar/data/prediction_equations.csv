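# Published prediction equations (coefficients as printed, 4 decimals).
# Evaluating these "as-printed" coefficients reproduces every published
# predicted pIC50; a fresh full-precision refit reproduces the published
# quality statistics.
model,p,intercept,ATM,ACC,DONN,ARO
mono,1,4.2566,0.1111,,,
bi,2,5.9493,0.0948,-0.3329,,
tri,3,6.0749,0.0849,-0.3338,0.3495,
tetra,4,6.1250,0.0907,-0.3721,0.3766,-0.0674
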