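# Docking binding energies (kcal/mol) used for the COX-2/COX-1 selectivity
# ratio report. COX-1 values are the published cross-docking energies against
# the ovine COX-1 structure; COX-2 values are the published affinities of the
# selected candidates. Indomethacin is the COX-1 crystallographic reference.
ligand,target,delta_g
Z-627,COX-2,-10.00
Z-964,COX-2,-9.50
Z-627,COX-1,-8.40
Z-964,COX-1,-8.60
Z-814,COX-1,-6.80
Indomethacin,COX-1,-10.70
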