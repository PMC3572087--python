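aa	n_atoms	charge	h_bonds	hydrophobicity	hydrophilicity	propensity	isoelectric_point	mass	contacts_14A	eiip
A	13	0	0	1.8	-0.5	1.42	6.00	89.09	6.50	0.0373
C	14	0	1	2.5	-1.0	0.70	5.05	121.15	7.38	0.0829
D	16	-1	4	-3.5	3.0	1.01	2.77	133.10	5.63	0.1263
E	19	-1	4	-3.5	3.0	1.51	3.22	147.13	5.44	0.0058
F	23	0	0	2.8	-2.5	1.13	5.48	165.19	7.36	0.0946
G	10	0	0	-0.4	0.0	0.57	5.97	75.07	6.16	0.0050
H	20	1	2	-3.2	-0.5	1.00	7.59	155.16	6.29	0.0242
I	22	0	0	4.5	-1.8	1.08	6.02	131.17	7.47	0.0000
K	24	1	2	-3.9	3.0	1.16	9.74	146.19	5.22	0.0371
L	22	0	0	3.8	-1.8	1.21	5.98	131.17	7.27	0.0000
M	20	0	0	1.9	-1.3	1.45	5.74	149.21	7.13	0.0823
N	17	0	4	-3.5	0.2	0.67	5.41	132.12	5.66	0.0036
P	17	0	0	-1.6	0.0	0.57	6.30	115.13	5.72	0.0198
Q	20	0	4	-3.5	0.2	1.11	5.65	146.15	5.62	0.0761
R	26	1	5	-4.5	3.0	0.98	10.76	174.20	5.68	0.0959
S	14	0	2	-0.8	0.3	0.77	5.68	105.09	6.02	0.0829
T	17	0	2	-0.7	-0.4	0.83	5.66	119.12	6.23	0.0941
V	19	0	0	4.2	-1.5	1.06	5.96	117.15	7.35	0.0057
W	27	0	1	-0.9	-3.4	1.08	5.89	204.24	7.20	0.0548
Y	24	0	2	-1.3	-2.3	0.69	5.66	181.19	6.77	0.0516
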