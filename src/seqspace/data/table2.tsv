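name	length	p_fs	source	printed_p_th	printed_rb_exponent	printed_n_min	printed_si	known_discrepancy
Membrane Embedding	50	1e-8	Knopp 2019	.0027	5	4	92
ATP Binding	80	1e-12	Keefe 2001	.0017	9	5	94	n_min
Chorismate Mutase	99	1e-23	Taylor 2001	.0013	20	11	89
WW	35	1e-24	Tian & Best 2017	.0038	21	15	57
Villin	35	1e-33	Tian & Best 2017	.0038	30	23	34
Titan I27	89	1e-38	Tian & Best 2017	.0015	35	20	78
TNfn3	90	1e-39	Tian & Best 2017	.0015	36	21	77
PDZ	94	1e-50	Tian & Best 2017	.0014	47	27	71	n_min
NTL9	56	1e-54	Tian & Best 2017	.0024	51	37	34	n_min
lambda-repressor	92	1e-63	Reidhaar-Olson & Sauer 1990	.0014	60	29	68	n_min
Cytochrome c	100	1e-65	Yockey 1977	.0013	62	38	62	n_min
beta-lactamase Domain	153	1e-77	Axe 2004	.00087	74	42	73	r_b
IM7	87	1e-86	Tian & Best 2017	.0015	74	59	32	n_min,r_b
IFABP	131	1e-111	Tian & Best 2017	.0010	108	71	46	n_min
alpha-LA	123	1e-121	Tian & Best 2017	.0011	118	83	33
OmpA	171	1e-126	Tian & Best 2017	.00078	123	77	55	r_b
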