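variable	median_record	median_recall	p_value	spearman_rho
Vegetables	117	130	.13	0.76
Fruit	83	130	.005	0.79
Added fats	12	17	.001	0.54
Meat	73	75	.10	0.70
Eggs	0	0	.44	0.76
Nuts	0	0	.73	0.84
Milk and milk products	219	252	.02	0.80
Cheese	30	31	.006	0.76
Bread	126	132	.95	0.85
Cereal products	6	20	.01	0.80
Potatoes	0	0	.96	0.88
Drinks	1836	1963	<.001	0.68
Sandwich spreads	0	0	.05	0.88
Snacks	52	56	.41	0.88
Sauces	2	22	<.001	0.60
Other	0	0	<.001	0.50
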