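gender	age_min	age_max	intercept_mj	coef_weight_mj_per_kg	coef_height_mj_per_m
man	18	30	0.473	0.0600	1.31
man	30	60	-0.574	0.0476	2.26
man	60	70	-1.070	0.0478	2.26
man	70	80	-1.259	0.0434	2.46
woman	18	30	-1.180	0.0433	2.57
woman	30	60	-0.0486	0.0342	2.10
woman	60	70	0.0448	0.0356	1.76
woman	70	80	0.0448	0.0356	1.76
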