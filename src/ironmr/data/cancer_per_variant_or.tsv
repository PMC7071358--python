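outcome	exposure	variant_id	or_point	ci_low	ci_high
liver_cancer	serum_iron	rs1800562	6.65	2.78	15.9
liver_cancer	serum_iron	rs1799945	1.01	0.32	3.16
liver_cancer	serum_iron	rs855791	1.54	0.65	3.64
liver_cancer	transferrin_saturation	rs1800562	2.94	1.79	4.82
liver_cancer	transferrin_saturation	rs1799945	1.01	0.40	2.56
liver_cancer	transferrin_saturation	rs855791	1.51	0.67	3.42
liver_cancer	log10_ferritin	rs1800562	21.0	5.18	85.4
liver_cancer	log10_ferritin	rs1799945	1.03	0.04	28.3
liver_cancer	log10_ferritin	rs855791	4.14	0.24	70.3
liver_cancer	transferrin	rs1800562	0.27	0.15	0.50
liver_cancer	transferrin	rs1799945	0.98	0.15	6.50
liver_cancer	transferrin	rs855791	0.17	0.01	5.82
brain_cancer	serum_iron	rs1800562	1.09	0.53	2.24
brain_cancer	serum_iron	rs1799945	0.54	0.31	0.95
brain_cancer	serum_iron	rs855791	0.67	0.39	1.16
brain_cancer	transferrin_saturation	rs1800562	1.07	0.59	1.93
brain_cancer	transferrin_saturation	rs1799945	0.69	0.41	1.16
brain_cancer	transferrin_saturation	rs855791	0.71	0.51	0.97
brain_cancer	log10_ferritin	rs1800562	1.28	0.16	10.4
brain_cancer	log10_ferritin	rs1799945	0.27	0.05	1.65
brain_cancer	log10_ferritin	rs855791	0.37	0.15	0.92
brain_cancer	transferrin	rs1800562	5.04	0.54	47.4
brain_cancer	transferrin	rs1799945	0.87	0.26	2.88
brain_cancer	transferrin	rs855791	1.52	1.04	2.23
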