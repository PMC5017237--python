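mutation_class	event	count	mean_age	flag
frameshift_insertion	dissection	3	30.0	.
frameshift_insertion	aneurysm	1	18.0	.
frameshift_insertion	valvular	1	33.0	.
frameshift_insertion	mild_dilation	1	27.0	.
frameshift_deletion	dissection	1	24.0	.
frameshift_deletion	aneurysm	2	18.5	.
frameshift_deletion	valvular	1	14.0	.
frameshift_deletion	mild_dilation	1	16.0	.
stopgain	dissection	6	33.2	.
stopgain	aneurysm	3	24.7	.
stopgain	valvular	2	31.5	.
stopgain	mild_dilation	1	17.0	.
splicing	dissection	5	33.6	.
splicing	aneurysm	3	38.0	.
splicing	valvular	1	16.0	.
splicing	mild_dilation	0	.	.
truncating_plus_splicing	dissection	15	32.1	.
truncating_plus_splicing	aneurysm	9	25.6	age_inconsistent
truncating_plus_splicing	valvular	5	25.2	.
truncating_plus_splicing	mild_dilation	3	20.0	.
missense	dissection	13	36.5	.
missense	aneurysm	12	33.4	.
missense	valvular	1	17.0	.
missense	mild_dilation	1	39.0	.
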