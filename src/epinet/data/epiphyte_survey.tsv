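locality	country	habitat	sampling	lat	long	network_size	NODF	NODF_significant	H2prime	Q	Q_significant
Tucumán	Argentina	TMF	GR	-26.76	-65.33	44	69.53	1	0.11	0.18	1
Quintana Roo	Mexico	LIF	na	19.38	-87.79	20	67.77	1	0.24	0.22	1
San Lorenzo	Panamá	TDF	CA+GR	8.3	-82.1	107	20.81	1	0.28	0.28	1
Cerro Quetzal	Mexico	ECF	CA	15.72	-92.92	25	59.89	0	0.10	0.13	1
Zamora	Ecuador	TMF	CA	-3.99	-76.1	146	56.98	1	0.21	0.17	1
Caulin Forest	Chile	TRF	GR	-41.83	-73.6	17	64.29	0	0.09	0.11	0
Senda Darwin	Chile	TRF	GR	-41.88	-73.67	16	74.65	1	0.09	0.09	0
Llanquihue	Chile	TRF	GR	-41.85	-73.57	22	74.54	1	0.06	0.08	0
Quilar	Chile	TRF	GR	-41.92	-73.60	19	68.95	0	0.12	0.12	1
Jalisco	Mexico	TDF	GR	20.66	-103.5	62	62.89	1	0.23	na	na
San Andrés Cal	Mexico	TDF	CA+GR	18.95	-99.08	16	76.67	1	0.1	0.09	1
Xishuangbanna	China	TMF	GR	22.01	100.8	180	16.4	1	0.5	na	na
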