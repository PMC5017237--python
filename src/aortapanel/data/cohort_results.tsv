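diagnosis	cases	pathogenic	vus	negative
Marfan syndrome	65	55	5	5
Suspected Marfan syndrome	52	29	7	16
Suspected Loeys-Dietz syndrome	10	3	7	0
Non-syndromic aortic events	121	5	51	65
Total	248	92	70	86
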