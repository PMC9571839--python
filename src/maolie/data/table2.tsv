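# Experimental inhibition constants and binding free energies, with LIE
# predictions and mean ligand RMSD over the production MD run.
# ki_um / ki_err_um in micromolar; energies in kcal/mol; rmsd in Angstrom.
# Note: the published dg_exp_err for compound 11 (0.01) is inconsistent with
# first-order propagation RT*sigma_Ki/Ki (~0.13); it is kept verbatim.
compound	charged	name	ki_um	ki_err_um	dg_exp	dg_exp_err	dg_calc	dg_calc_err	rmsd
1	0	norharman	3.34	0.10	-7.6	0.02	-7.9	0.5	3.7
2	1	2-methyl-norharmanium	1.43	0.09	-8.1	0.04	-9.3	0.6	1.1
3	0	harman	0.26	0.024	-9.1	0.06	-9.1	0.3	1.9
4	1	2-methyl-harmanium	0.68	0.026	-8.6	0.02	-8.6	0.6	1.5
5	1	2,9-dimethyl-harmanium	0.16	0.036	-9.4	0.14	-9.6	0.6	1.6
6	0	harmine	0.005	0.0002	-11.5	0.02	-10.0	0.4	2.3
7	1	2-methyl-harminium	0.069	0.008	-9.9	0.07	-9.0	1.2	1.7
8	1	2,9-dimethyl-harminium	0.015	0.0008	-10.9	0.03	-9.4	0.6	1.4
9	0	harmaline	0.048	0.007	-10.2	0.09	-10.6	0.6	1.9
10	0	6-methoxy-harmalan	0.39	0.052	-8.9	0.08	-10.1	0.4	3.7
11	1	2-methyl-6-methoxy-harmalanium	1.23	0.27	-8.2	0.01	-8.5	0.3	3.5
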