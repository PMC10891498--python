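variable	unit	median_record	median_recall	p_value	spearman_rho
Energy	kcal	1994	1994	.59	0.75
Fat	g	76	81	.001	0.74
Saturated fatty acids	g	27	28	.01	0.70
Protein	g	77	77	.54	0.70
Vegetable protein	g	30	30	.37	0.75
Carbohydrates	g	215	208	.04	0.78
Mono- and disaccharides	g	81	80	.01	0.80
Fiber	g	20	20	.15	0.75
Alcohol	g	0	0	.45	0.92
Water	g	2570	2775	<.001	0.68
Vitamin A	ug_RAE	453	515	<.001	0.74
Vitamin B1	mg	0.9	0.9	.21	0.63
Vitamin B2	mg	1.3	1.3	.002	0.73
Vitamin B3	mg	16.5	17.3	.17	0.70
Vitamin B6	mg	1.4	1.5	<.001	0.71
Folate equivalents	ug	241	269	<.001	0.67
Vitamin B12	ug	2.9	3.2	.001	0.78
Vitamin C	mg	65	67	.09	0.77
Vitamin D	ug	1.8	2.1	<.001	0.64
Vitamin E	mg	9.7	11.7	<.001	0.58
Calcium	mg	909	921	.12	0.74
Iodine	ug	159	162	.42	0.80
Iron	mg	9.3	9.4	.41	0.73
Magnesium	mg	334	328	.04	0.72
Phosphorus	mg	1466	1478	.63	0.72
Potassium	mg	3147	3106	.38	0.72
Selenium	ug	43	43	.60	0.68
Sodium	mg	2373	2283	.05	0.55
Zinc	mg	9.4	10.0	.10	0.70
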