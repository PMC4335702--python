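locus	motif	repeat_count	N	k	Ho	He	AR	PIC	hwe_p
gpz-6	AAAG	11	56	6	0.714	0.689	6.000	0.633	0.2615
gpz-47	AATG	20	57	4	0.544	0.524	4.000	0.468	0.3557
gpz-20	AAAG	10	52	10	0.731	0.724	10.000	0.695	0.1302
GPL-47	TCTA	20	53	6	0.849	0.819	6.000	0.783	0.2161
GPL-29	ATCC	19	56	4	0.714	0.677	4.000	0.617	0.2800
GPL-60	TCTT	12	57	5	0.702	0.719	5.000	0.668	0.3991
gpz-54	AGAT	18	56	5	0.714	0.704	4.929	0.643	0.6226
GPL-8	ATCC	11	54	4	0.648	0.639	4.000	0.584	0.4311
GPL-31	ATCT	21	57	3	0.632	0.585	3.000	0.490	0.1640
GPL-44	ATAA	21	53	3	0.491	0.525	3.000	0.461	0.2543
gpz-51	AGAT	11	57	4	0.579	0.503	3.993	0.424	0.0440
GPL-28	ATAA	21	56	3	0.536	0.486	2.995	0.382	0.2594
GPL-53	ATTT	21	55	6	0.382	0.380	5.997	0.362	0.6395
gpy-20	TTTG	16	56	3	0.482	0.492	3.000	0.439	0.8984
gpy-5	AACT	16	57	4	0.509	0.510	3.993	0.459	0.4341
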