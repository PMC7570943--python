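# Physicochemical profiles of the candidate inhibitors and controls
# (Molinspiration-style columns). n_violations is the published Lipinski
# violation count; the package recomputes it from mw/milogp/n_hd/n_ha.
id,milogp,tpsa,mw,n_ha,n_hd,n_violations,n_rotb,volume
Rofecoxib,0.71,60.45,314.36,4,0,0,3,264.79
Celecoxib,3.61,77.99,381.38,5,2,0,4,298.65
Z-814,3.35,68.28,408.39,4,0,0,6,299.11
Z-627,1.38,75.27,330.41,5,2,0,4,286.58
Z-964,2.03,58.20,384.47,4,2,0,7,316.16
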