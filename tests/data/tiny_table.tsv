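accession	gene_symbol	confidence	unique_peptides	description	set1.run1.126	set1.run1.127N	set1.run1.127C	set1.run1.128N	set1.run1.128C	set1.run1.129N	set1.run1.129C	set1.run1.130N	set1.run1.130C	set1.run1.131	set1.run2.126	set1.run2.127N	set1.run2.127C	set1.run2.128N	set1.run2.128C	set1.run2.129N	set1.run2.129C	set1.run2.130N	set1.run2.130C	set1.run2.131
P00001	p00001	high	4	toy protein P00001	101	111	121	131	141	151	161	171	181	191	102	112	122	132	142	152	162	172	182	192
P00002	p00002	high	1	toy protein P00002		261	271	281	291	301	311	321	331	341	252	262	272	282	292	302	312	322	332	342
P00003	p00003	medium	0	toy protein P00003	41	51	61	71	81	91	101	111	121	131	42	52	62	72	82	92	102	112	122	132
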