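# Per-compound MD interaction-energy decomposition, kcal/mol.
# Columns: bound/free means with block-average SDs for the vdW and
# electrostatic components, plus bound-minus-free difference columns as
# printed (difference SDs equal the bound-state SDs because free-state
# fluctuations are ~0.1-0.2 kcal/mol).  charged=1 marks N-methyl-pyridinium
# compounds.
compound	charged	vdw_bound	vdw_bound_sd	vdw_free	vdw_free_sd	dvdw	dvdw_sd	el_bound	el_bound_sd	el_free	el_free_sd	del	del_sd
1	0	-28.4	0.5	-15.4	0.1	-13.1	0.5	-15.1	1.6	-22.2	0.1	7.1	1.6
2	1	-36.7	0.5	-17.9	0.1	-18.9	0.5	-84.1	2.2	-98.0	0.2	13.9	2.2
3	0	-32.5	0.3	-16.8	0.1	-15.7	0.3	-15.7	0.9	-23.6	0.1	7.9	0.9
4	1	-38.2	0.8	-19.4	0.1	-17.7	0.8	-82.9	1.6	-96.9	0.1	14.0	1.6
5	1	-39.8	1.0	-22.7	0.1	-17.1	1.0	-77.6	0.7	-86.5	0.2	8.9	0.7
6	0	-36.9	0.4	-19.6	0.1	-17.2	0.4	-17.0	1.2	-24.5	0.1	7.2	1.2
7	1	-42.3	1.0	-22.0	0.1	-20.3	1.0	-78.9	4.1	-96.7	0.2	17.8	4.1
8	1	-43.9	0.7	-25.3	0.1	-18.6	0.7	-74.5	1.6	-87.5	0.2	12.9	1.6
9	0	-41.9	1.0	-20.6	0.1	-21.2	1.0	-9.7	0.6	-23.4	0.1	13.7	0.6
10	0	-39.5	0.6	-20.7	0.1	-18.8	0.6	-12.9	0.7	-23.3	0.1	10.4	0.7
11	1	-41.0	0.2	-22.6	0.1	-18.4	0.2	-81.1	1.1	-96.8	0.2	15.7	1.1
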