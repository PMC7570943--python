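# Published MM-GBSA binding free energies (kcal/mol) of the ligand/COX-2
# systems from 100 ns trajectories. Reference values for reporting only;
# they are not desk-scale reproducible. Where the prose and the table
# disagree on ligand assignment, the table is stored as authoritative.
organism,ligand,delta_g_bind
Homo sapiens,Rofecoxib,-48.15
Homo sapiens,Z-814,-45.51
Homo sapiens,Z-627,-42.76
Mus musculus,Celecoxib,-47.78
Mus musculus,Z-627,-41.63
Mus musculus,Z-964,-44.27
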