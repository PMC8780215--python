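subject_id	group	gender	hand	level	ais	age	years_injury	grassp	grip_kg	pinch_kg	mune	cmap_mV	d50
S01	SCI	M	R	C7	B	57	24	70	0.9	0	28	4.23	17
S02	SCI	M	R	C5	D	62	10	84	15.2	4.5	42	9.21	52
S03	SCI	M	R	C6	B	21	3	34	0	0	75	8.80	56
S04	SCI	F	R	C5	C	57	1	57	2.3	1.8	141	8.46	44
S05	SCI	F	R	C5	B	39	16	31	0	0	30	4.64	32
S06	SCI	M	R	C5	D	24	1	108	45.4	11.3	74	18.04	38
S07	SCI	M	R	C4	C	53	30	90	15.4	5.0	35	5.51	35
S08	SCI	M	L	C4	D	59	3	83	19.5	8.2	41	11.81	28
S09	SCI	M	R	C1	A	21	1	0	0	0	107	8.37	71
S10	SCI	M	R	C6	C	45	4	79	0	1.4	5	1.78	2
S11	SCI	M	R	C3	C	35	15	7	0	0	76	8.38	39
S12	SCI	F	R	C3	C	54	2	4	0	0	75	6.94	43
S13	SCI	M	R	C3	D	37	13	96	9.8	3.0	43	8.00	27
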