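variant_id	gene	effect_allele	eaf	trait	beta	se	pvalue
rs1800562	HFE	A	0.07	serum_iron	0.328	0.016	2.9e-97
rs1799945	HFE	G	0.15	serum_iron	0.189	0.010	1.1e-81
rs855791	TMPRSS6	G	0.55	serum_iron	0.181	0.007	4.3e-139
rs8177240	TF	G	0.35	serum_iron	0.066	0.007	6.6e-20
rs7385804	TFR2	A	0.62	serum_iron	0.064	0.007	1.4e-18
rs1800562	HFE	A	0.07	transferrin_saturation	0.577	0.016	2.2e-270
rs1799945	HFE	G	0.15	transferrin_saturation	0.231	0.010	5.1e-109
rs855791	TMPRSS6	G	0.55	transferrin_saturation	0.190	0.007	6.4e-137
rs8177240	TF	G	0.35	transferrin_saturation	0.100	0.008	7.2e-38
rs7385804	TFR2	A	0.62	transferrin_saturation	0.054	0.008	6.1e-12
rs1800562	HFE	A	0.07	log10_ferritin	0.204	0.016	1.5e-38
rs1799945	HFE	G	0.15	log10_ferritin	0.065	0.010	1.7e-10
rs855791	TMPRSS6	G	0.55	log10_ferritin	0.055	0.007	1.4e-14
rs744653	AC013439.4	C	0.16	log10_ferritin	0.089	0.010	8.4e-19
rs411988	TEX14	G	0.44	log10_ferritin	0.044	0.007	1.6e-10
rs651007	ABO	C	0.79	log10_ferritin	0.050	0.009	1.3e-8
rs1800562	HFE	A	0.07	transferrin	-0.479	0.016	8.9e-196
rs1799945	HFE	G	0.15	transferrin	-0.114	0.010	9.4e-30
rs855791	TMPRSS6	G	0.55	transferrin	-0.044	0.007	2.0e-9
rs8177240	TF	G	0.35	transferrin	0.380	0.007	8.4e-610
rs4921915	NAT2	A	0.76	transferrin	0.079	0.009	7.1e-19
rs174577	FADS2	A	0.36	transferrin	0.062	0.007	2.3e-17
rs9990333	TFRC	C	0.53	transferrin	0.051	0.007	2.0e-13
rs6486121	ARNTL	C	0.34	transferrin	0.046	0.007	3.9e-10
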