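outcome	exposure	row	value	ci_low	ci_high	p
liver_cancer	serum_iron	ivw_random	2.45	0.81	7.45	0.11
liver_cancer	transferrin_saturation	ivw_random	2.11	1.16	3.83	0.01
liver_cancer	log10_ferritin	ivw_random	10.9	2.44	48.6	2.00e-3
liver_cancer	transferrin	ivw_random	0.30	0.17	0.53	2.99e-5
liver_cancer	serum_iron	weighted_median	2.08	0.97	4.47	0.06
liver_cancer	transferrin_saturation	weighted_median	2.14	1.39	3.31	1.00e-3
liver_cancer	log10_ferritin	weighted_median	12.1	3.24	45.2	3.43e-4
liver_cancer	transferrin	weighted_median	0.30	0.17	0.53	3.31e-5
liver_cancer	serum_iron	mr_egger	49.0	5.64	424	4.17e-4
liver_cancer	transferrin_saturation	mr_egger	4.36	1.87	10.1	1.00e-3
liver_cancer	log10_ferritin	mr_egger	46.4	5.47	394	4.38e-4
liver_cancer	transferrin	mr_egger	0.28	0.11	0.70	7.00e-3
liver_cancer	serum_iron	heterogeneity	76	23	93	0.01
liver_cancer	transferrin_saturation	heterogeneity	58	0	88	0.09
liver_cancer	log10_ferritin	heterogeneity	38	0	81	0.20
liver_cancer	transferrin	heterogeneity	0	0	90	0.43
liver_cancer	serum_iron	pleiotropy_intercept	-0.662	-1.124	-0.199	5.00e-3
liver_cancer	transferrin_saturation	pleiotropy_intercept				0.06
liver_cancer	log10_ferritin	pleiotropy_intercept				0.11
liver_cancer	transferrin	pleiotropy_intercept				0.76
brain_cancer	serum_iron	ivw_random	0.69	0.48	1.00	0.05
brain_cancer	transferrin_saturation	ivw_random	0.75	0.59	0.97	0.03
brain_cancer	log10_ferritin	ivw_random	0.41	0.20	0.88	0.02
brain_cancer	transferrin	ivw_random	1.49	1.04	2.14	0.03
brain_cancer	serum_iron	weighted_median	0.65	0.44	0.96	0.03
brain_cancer	transferrin_saturation	weighted_median	0.71	0.53	0.93	0.02
brain_cancer	log10_ferritin	weighted_median	0.37	0.16	0.83	0.02
brain_cancer	transferrin	weighted_median	1.46	1.01	2.13	0.05
brain_cancer	serum_iron	mr_egger	0.35	0.07	1.63	0.18
brain_cancer	transferrin_saturation	mr_egger	0.68	0.36	1.29	0.24
brain_cancer	log10_ferritin	mr_egger	0.36	0.08	1.69	0.19
brain_cancer	transferrin	mr_egger	1.38	0.74	2.57	0.31
brain_cancer	serum_iron	heterogeneity	11	0	91	0.33
brain_cancer	transferrin_saturation	heterogeneity	0	0	90	0.44
brain_cancer	log10_ferritin	heterogeneity	0	0	90	0.51
brain_cancer	transferrin	heterogeneity	0	0	90	0.38
brain_cancer	serum_iron	pleiotropy_intercept				0.37
brain_cancer	transferrin_saturation	pleiotropy_intercept				0.72
brain_cancer	log10_ferritin	pleiotropy_intercept				0.82
brain_cancer	transferrin	pleiotropy_intercept				0.72
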