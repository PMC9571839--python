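# Declarative ligand pharmacophore feature annotations for the harmine-like
# beta-carboline template used by the toy pocket generator (synthetic atom
# naming).  Columns: feature_id, type, comma-separated ligand atom names.
# Types: hydrophobic, hbond_donor, hbond_acceptor, positive_ionizable, aromatic.
feature_id	type	atoms
pyridine_n	hbond_acceptor	N1
pyrrole_nh	hbond_donor	N9
pyridine_ring	hydrophobic	C2,C3,C4,C4A,C9A
benzene_ring	hydrophobic	C5,C6,C7,C8
c1_methyl	hydrophobic	CM1
methoxy_o	hbond_acceptor	OM
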