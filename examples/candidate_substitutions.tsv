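gene_id	fly_ortholog	position	ref_aa	alt_aa	d_af	provean	sift
LOC123760978	CG31743	10	V	F	0.51	-0.71	0.03
LOC123756530	CG9372	149	F	L	0.65	0.48	0
LOC123761000	NA	175	L	F	0.88	-4.00	NA
LOC123758696	JIL-1	227	T	S	0.87	-0.28	0
LOC123758717	peng	16	Q	R	0.78	-0.20	0
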